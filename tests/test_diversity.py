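import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from fungalnet.diversity import (DistanceMatrix, alpha_diversity,
                                 alpha_diversity_frame, anosim, bray_curtis,
                                 kruskal_wallis, pairwise_anosim, pcoa,
                                 permanova)
from fungalnet.tables import OTUTable


def make_table(columns: dict) -> OTUTable:
    return OTUTable(pd.DataFrame(columns))


class TestAlphaDiversity:
    def test_uniform_sample_closed_forms(self):
        table = make_table({"A": [5] * 10})
        rec = alpha_diversity(table)[0]
        assert rec.shannon == pytest.approx(np.log(10), abs=1e-12)
        assert rec.simpson == pytest.approx(0.9, abs=1e-12)
        assert rec.evenness == pytest.approx(1.0, abs=1e-12)
        assert rec.richness == 10

    def test_single_otu_sample(self):
        rec = alpha_diversity(make_table({"A": [42]}))[0]
        assert rec.shannon == 0.0
        assert rec.simpson == 0.0

    def test_chao1_bias_corrected_by_hand(self):
        # S_obs=10, F1=4, F2=2 → 10 + 4·3/(2·3) = 12
        counts = [1, 1, 1, 1, 2, 2, 5, 6, 7, 8]
        rec = alpha_diversity(make_table({"A": counts}))[0]
        assert rec.chao1 == pytest.approx(12.0)
        assert rec.chao1 >= rec.richness

    def test_matches_scikit_bio(self, synth_table):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        ours = alpha_diversity_frame(synth_table)
        for s in synth_table.sample_ids[:4]:
            counts = synth_table.counts[s].to_numpy()
            assert ours.loc[s, "shannon"] == pytest.approx(
                float(skbio_alpha.shannon(counts, base=np.e)), rel=1e-10)
            assert ours.loc[s, "chao1"] == pytest.approx(
                float(skbio_alpha.chao1(counts, bias_corrected=True)), rel=1e-10)
            assert ours.loc[s, "ace"] == pytest.approx(
                float(skbio_alpha.ace(counts, rare_threshold=10)), rel=1e-6)

    def test_row_order_invariance(self, synth_table):
        shuffled = synth_table.subset_otus(
            list(reversed(synth_table.otu_ids)))
        a = alpha_diversity_frame(synth_table)
        b = alpha_diversity_frame(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_sample_rejected_at_table_construction(self):
        with pytest.raises(ValueError, match="zero total"):
            make_table({"A": [1, 2], "B": [0, 0]})


class TestKruskalWallis:
    def test_hand_value(self):
        h, p = kruskal_wallis([1, 2, 3, 4, 5, 6, 7, 8, 9],
                              ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert h == pytest.approx(7.2)
        assert p == pytest.approx(0.0273, abs=1e-4)

    def test_all_equal_gives_p_one(self):
        h, p = kruskal_wallis([5.0] * 6, ["a"] * 3 + ["b"] * 3)
        assert h == 0.0
        assert p == 1.0

    def test_matches_scipy_with_ties(self, rng):
        values = rng.integers(0, 5, size=30).astype(float)
        labels = np.array(["a", "b", "c"] * 10)
        h, p = kruskal_wallis(values, labels)
        ref = stats.kruskal(*(values[labels == g] for g in "abc"))
        assert h == pytest.approx(float(ref.statistic), rel=1e-12)
        assert p == pytest.approx(float(ref.pvalue), rel=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2, 3], ["a", "a", "a"])


class TestBrayCurtis:
    def test_hand_value_and_extremes(self):
        table = make_table({"x": [1, 1, 0], "y": [0, 1, 1], "z": [1, 1, 0]})
        dm = bray_curtis(table)
        assert dm.values[0, 1] == pytest.approx(0.5)
        assert dm.values[0, 2] == pytest.approx(0.0)   # identical columns
        disjoint = make_table({"x": [3, 0], "y": [0, 7]})
        assert bray_curtis(disjoint).values[0, 1] == pytest.approx(1.0)

    def test_metric_properties(self, synth_table):
        dm = bray_curtis(synth_table)
        assert np.allclose(dm.values, dm.values.T)
        assert (dm.values >= 0).all() and (dm.values <= 1).all()
        assert np.allclose(np.diag(dm.values), 0.0)


class TestPCoA:
    def test_collinear_points_single_axis(self):
        pts = np.array([[0.0], [1.0], [3.0], [7.0]])
        d = squareform(pdist(pts))
        coords, explained = pcoa(DistanceMatrix(list("abcd"), d))
        assert explained[0] == pytest.approx(1.0, abs=1e-10)

    def test_euclidean_distances_recovered(self, rng):
        pts = rng.normal(size=(8, 3))
        d = squareform(pdist(pts))
        coords, _ = pcoa(DistanceMatrix([str(i) for i in range(8)], d))
        d_rec = squareform(pdist(coords.to_numpy()))
        assert np.allclose(d, d_rec, atol=1e-8)

    def test_matches_scikit_bio_on_bray_curtis(self, synth_table):
        skbio = pytest.importorskip("skbio")
        dm = bray_curtis(synth_table)
        ours_coords, ours_explained = pcoa(dm)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.values, dm.labels))
        n_axes = min(3, ours_coords.shape[1])
        for i in range(n_axes):
            assert ours_explained[i] == pytest.approx(
                float(ref.proportion_explained.iloc[i]), abs=1e-6)
            # eigenvectors are sign-arbitrary
            ref_axis = ref.samples.iloc[:, i].to_numpy()
            ours_axis = ours_coords.iloc[:, i].to_numpy()
            assert (np.allclose(ours_axis, ref_axis, atol=1e-6)
                    or np.allclose(ours_axis, -ref_axis, atol=1e-6))

    def test_explained_proportions_bounded(self, synth_table):
        _, explained = pcoa(bray_curtis(synth_table))
        assert explained.sum() == pytest.approx(1.0, abs=1e-9)
        assert (explained >= 0).all()


def _two_cluster_dm(n_per=10, sep=10.0, rng=None):
    rng = rng or np.random.default_rng(0)
    pts = np.vstack([rng.normal(0, 0.1, size=(n_per, 2)),
                     rng.normal(sep, 0.1, size=(n_per, 2))])
    labels = ["a"] * n_per + ["b"] * n_per
    return DistanceMatrix([str(i) for i in range(2 * n_per)],
                          squareform(pdist(pts))), labels


class TestPermanova:
    def test_separated_clusters_hit_minimum_p(self):
        dm, labels = _two_cluster_dm()
        _, p = permanova(dm, labels, n_perm=199, seed=1)
        assert p == pytest.approx(1.0 / 200.0)

    def test_deterministic_given_seed(self, synth_table):
        dm = bray_curtis(synth_table)
        labels = [m.group for m in synth_table.metadata]
        r1 = permanova(dm, labels, n_perm=99, seed=5)
        r2 = permanova(dm, labels, n_perm=99, seed=5)
        assert r1 == r2

    def test_statistic_matches_scikit_bio(self, synth_table):
        skbio = pytest.importorskip("skbio")
        dm = bray_curtis(synth_table)
        labels = [m.group for m in synth_table.metadata]
        f_obs, _ = permanova(dm, labels, n_perm=99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.values, dm.labels), labels,
            permutations=9)
        assert f_obs == pytest.approx(float(ref["test statistic"]), rel=1e-10)

    def test_p_never_below_permutation_floor(self):
        dm, labels = _two_cluster_dm()
        _, p = permanova(dm, labels, n_perm=99, seed=0)
        assert p >= 1.0 / 100.0


class TestAnosim:
    def test_fully_separated_r_is_one(self):
        dm, labels = _two_cluster_dm()
        r, p = anosim(dm, labels, n_perm=199, seed=1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1.0 / 200.0)

    def test_statistic_matches_scikit_bio(self, synth_table):
        skbio = pytest.importorskip("skbio")
        dm = bray_curtis(synth_table)
        labels = [m.group for m in synth_table.metadata]
        r_obs, _ = anosim(dm, labels, n_perm=99, seed=0)
        ref = skbio.stats.distance.anosim(
            skbio.DistanceMatrix(dm.values, dm.labels), labels,
            permutations=9)
        assert r_obs == pytest.approx(float(ref["test statistic"]), rel=1e-10)

    def test_r_bounded(self, rng):
        pts = rng.normal(size=(12, 3))
        dm = DistanceMatrix([str(i) for i in range(12)],
                            squareform(pdist(pts)))
        labels = list("aabbcc") * 2
        r, _ = anosim(dm, labels, n_perm=99, seed=2)
        assert -1.0 <= r <= 1.0

    def test_pairwise_reports_all_pairs_with_fdr(self, synth_table):
        dm = bray_curtis(synth_table)
        labels = [m.group for m in synth_table.metadata]
        out = pairwise_anosim(dm, labels, n_perm=99, seed=0)
        assert len(out) == 3
        assert (out["p_adjusted"] >= out["p"] - 1e-12).all()
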