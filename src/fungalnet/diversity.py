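"""Alpha and beta diversity with permutation tests.

Alpha indices follow the conventional definitions used across community
ecology: Shannon in natural-log units, Simpson as the Gini–Simpson
complement 1 − Σp², bias-corrected Chao1, and the abundance-based coverage
estimator (ACE) with the usual rare-abundance cutoff of 10.  Beta diversity
is Bray–Curtis dissimilarity, ordinated by classical principal-coordinates
analysis, with PERMANOVA (Anderson's pseudo-F) and ANOSIM permutation
tests implemented directly so every rank, sum of squares and permutation
scheme is explicit and seedable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .tables import OTUTable


@dataclass(frozen=True)
class AlphaDiversityRecord:
    sample_id: str
    richness: int
    chao1: float
    ace: float
    shannon: float
    simpson: float
    evenness: float


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample dissimilarities with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("distance matrix must be square and match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def _chao1(counts: np.ndarray) -> float:
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def _ace(counts: np.ndarray, rare_cutoff: int = 10) -> float:
    counts = counts[counts > 0]
    rare = counts[counts <= rare_cutoff]
    abund = counts[counts > rare_cutoff]
    s_rare, s_abund = len(rare), len(abund)
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        # all rare taxa are singletons; ACE is undefined, fall back to Chao1
        return _chao1(counts)
    fi = np.array([(rare == i).sum() for i in range(1, rare_cutoff + 1)])
    i = np.arange(1, rare_cutoff + 1)
    gamma2 = max(
        (s_rare / c_ace) * (i * (i - 1) @ fi) / (n_rare * (n_rare - 1)) - 1.0
        if n_rare > 1 else 0.0,
        0.0,
    )
    return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2


def alpha_diversity(table: OTUTable) -> list[AlphaDiversityRecord]:
    """Per-sample richness, Chao1, ACE, Shannon (ln), Gini-Simpson, evenness."""
    records = []
    for s in table.sample_ids:
        counts = table.counts[s].to_numpy()
        n = counts.sum()
        if n <= 0:
            raise ValueError(f"sample {s} is empty")
        pos = counts[counts > 0]
        p = pos / n
        richness = len(pos)
        shannon = float(-(p * np.log(p)).sum())
        simpson = float(1.0 - (p ** 2).sum())
        evenness = shannon / np.log(richness) if richness > 1 else 0.0
        records.append(AlphaDiversityRecord(
            sample_id=s, richness=richness, chao1=_chao1(counts),
            ace=_ace(counts), shannon=shannon, simpson=simpson,
            evenness=float(evenness),
        ))
    return records


def alpha_diversity_frame(table: OTUTable) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in alpha_diversity(table)]).set_index("sample_id")


def kruskal_wallis(values, labels) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p (df = k−1)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    n = len(values)
    ranks = stats.rankdata(values)
    h = 12.0 / (n * (n + 1)) * sum(
        ranks[labels == g].sum() ** 2 / (labels == g).sum() for g in groups
    ) - 3 * (n + 1)
    _, tie_counts = np.unique(values, return_counts=True)
    correction = 1.0 - ((tie_counts ** 3 - tie_counts).sum()) / (n ** 3 - n)
    if correction == 0.0:          # all observations identical
        return 0.0, 1.0
    h /= correction
    p = float(stats.chi2.sf(h, df=len(groups) - 1))
    return float(h), p


# ---------------------------------------------------------------------------
# Beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(table: OTUTable) -> DistanceMatrix:
    """Bray–Curtis dissimilarity Σ|x−y| / Σ(x+y) between sample columns."""
    if table.shape[1] < 2:
        raise ValueError("need at least two samples")
    mat = table.counts.to_numpy().T.astype(float)
    d = squareform(pdist(mat, metric="braycurtis"))
    return DistanceMatrix(table.sample_ids, d)


def pcoa(dm: DistanceMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical (Torgerson) scaling of a distance matrix.

    Returns (coordinates, explained) where coordinates hold one column per
    retained positive eigenvalue (axis1, axis2, …) and ``explained`` gives
    each axis's share of the positive eigenvalue total.  Negative
    eigenvalues (possible for non-Euclidean dissimilarities such as
    Bray–Curtis) are dropped.
    """
    d2 = dm.values ** 2
    n = dm.n
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-10
    pos = eigvals > tol
    lam = eigvals[pos]
    coords = eigvecs[:, pos] * np.sqrt(lam)
    explained = lam / lam.sum()
    frame = pd.DataFrame(
        coords, index=dm.labels,
        columns=[f"axis{i + 1}" for i in range(coords.shape[1])],
    )
    return frame, explained


def _group_onehot(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    groups, idx = np.unique(labels, return_inverse=True)
    onehot = np.zeros((len(labels), len(groups)))
    onehot[np.arange(len(labels)), idx] = 1.0
    return onehot, groups


def _permanova_f(d2: np.ndarray, onehot: np.ndarray) -> float:
    n = d2.shape[0]
    k = onehot.shape[1]
    ss_total = d2.sum() / (2.0 * n)
    sizes = onehot.sum(axis=0)
    within = np.einsum("ik,ij,jk->k", onehot, d2, onehot) / 2.0
    ss_within = (within / sizes).sum()
    ss_between = ss_total - ss_within
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def permanova(dm: DistanceMatrix, labels, n_perm: int = 999,
              seed: int = 0) -> tuple[float, float]:
    """One-way PERMANOVA: Anderson's pseudo-F with a seeded permutation p.

    p = (1 + #{permuted F ≥ observed}) / (1 + n_perm), never zero.
    """
    labels = np.asarray(labels)
    if len(labels) != dm.n:
        raise ValueError("labels must match distance matrix")
    onehot, groups = _group_onehot(labels)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    if (onehot.sum(axis=0) < 2).any():
        warnings.warn("a group has a single sample; pseudo-F is unstable")
    d2 = dm.values ** 2
    f_obs = _permanova_f(d2, onehot)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(dm.n)
        if _permanova_f(d2, onehot[perm]) >= f_obs:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return float(f_obs), float(p)


def _anosim_r(rank_sq: np.ndarray, same_group: np.ndarray, m: int) -> float:
    triu = np.triu_indices_from(rank_sq, k=1)
    within = same_group[triu]
    r_within = rank_sq[triu][within].mean()
    r_between = rank_sq[triu][~within].mean()
    return (r_between - r_within) / (m / 2.0)


def anosim(dm: DistanceMatrix, labels, n_perm: int = 999,
           seed: int = 0) -> tuple[float, float]:
    """ANOSIM R = (mean between-group rank − mean within-group rank)/(M/2)."""
    labels = np.asarray(labels)
    if len(labels) != dm.n:
        raise ValueError("labels must match distance matrix")
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    n = dm.n
    m = n * (n - 1) // 2
    triu = np.triu_indices(n, k=1)
    ranks = stats.rankdata(dm.values[triu])
    rank_sq = np.zeros((n, n))
    rank_sq[triu] = ranks
    rank_sq += rank_sq.T
    same = labels[:, None] == labels[None, :]
    r_obs = _anosim_r(rank_sq, same, m)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        lab = labels[perm]
        if _anosim_r(rank_sq, lab[:, None] == lab[None, :], m) >= r_obs:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return float(r_obs), float(p)


def pairwise_anosim(dm: DistanceMatrix, labels, n_perm: int = 999,
                    seed: int = 0) -> pd.DataFrame:
    """ANOSIM over every group pair, with raw and BH-adjusted p-values."""
    from .compare import bh_fdr

    labels = np.asarray(labels)
    groups = sorted(np.unique(labels))
    rows = []
    rng = np.random.default_rng(seed)
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            mask = np.isin(labels, [a, b])
            idx = np.where(mask)[0]
            sub = DistanceMatrix(
                [dm.labels[i] for i in idx], dm.values[np.ix_(idx, idx)]
            )
            r, p = anosim(sub, labels[idx], n_perm=n_perm,
                          seed=int(rng.integers(2 ** 31)))
            rows.append({"group_a": a, "group_b": b, "R": r, "p": p})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bh_fdr(out["p"].tolist())
    return out
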