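# Methods

This note documents the models, conventions, numerical choices and known
limitations of `fungalnet`, in the spirit of the methods documentation of
mature analysis packages. It states nothing the tests and scripts do not
themselves compute.

## Data model

The universal currency is the `OTUTable`: a non-negative integer
OTU × sample matrix with a `TaxonomyLineage` per OTU (ordered
kingdom→species, any unresolved suffix absent) and a metadata record
(group, timepoint) per sample. Every column must have positive depth.
TSV is the primary dialect (`#OTU ID`, one column per sample, trailing
semicolon-delimited `taxonomy` with `k__/p__/…` prefixes); BIOM v1 JSON
(dense or sparse) is accepted read-only. Writers mirror readers
bit-exactly for integer counts.

## Normalisation

Rarefaction subsamples each sample's reads to a common depth **without
replacement** (multivariate hypergeometric draw), in one pass, seeded —
so "normalised to the minimum sample size" is exactly reproducible and
never invents reads. Depth above any sample's total is an error naming
the sample.

## Diversity

Alpha indices follow the dominant conventions and say so explicitly,
because index names alone underdetermine them:

* Shannon H = −Σ pᵢ ln pᵢ (natural log).
* Simpson is reported as Gini–Simpson, 1 − Σ pᵢ².
* Chao1 uses the bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)), which is
  finite at F₂ = 0 and never below observed richness.
* ACE uses the standard abundance-based coverage estimator with rare
  cutoff 10; if every rare taxon is a singleton (C_ACE = 0) it falls back
  to Chao1.
* Evenness = H/ln(S). Published evenness values of ~0.96 alongside
  H ≈ 4.6 and S ≈ 1000 are not consistent with H/ln(S) (≈ 0.67), so the
  variant used there is evidently different and unstated; we implement
  the textbook Pielou form and document the discrepancy rather than
  reverse-engineer one number.

Beta diversity is Bray–Curtis on (rarefied) counts. PCoA is classical
Torgerson scaling: double-centre −½D², eigendecompose, scale eigenvectors
by √λ; negative eigenvalues (possible for non-Euclidean dissimilarities)
are dropped and explained proportions are taken over the positive
spectrum only.

PERMANOVA (Anderson's one-way pseudo-F from total and within-group sums
of squared distances) and ANOSIM (R = (r̄_between − r̄_within)/(M/2) on
midranked distances) are implemented directly rather than wrapped, so the
permutation scheme is explicit: labels are permuted `n_perm` times
(default 999) from a caller-supplied seed and
p = (1 + #{stat_perm ≥ stat_obs})/(1 + n_perm), which can never be zero.
scikit-bio's implementations serve as independent cross-checks in the
test suite; the type-I error of both tests is verified to sit at the
nominal 5% level by simulation. Pairwise ANOSIM reports raw and
BH-adjusted p-values, since published pairwise values rarely state a
correction.

## Differential composition

Group tests at a taxonomic rank run on per-sample relative abundances:
Kruskal–Wallis (tie-corrected, χ² reference) across all groups, Welch's
t for pairwise and one-vs-rest contrasts, BH-FDR across taxa within a
contrast (not across contrasts).

The volcano-style differential-OTU screen deliberately does **not**
re-implement negative-binomial count machinery. The decision rule — fold
change > 4 and p < 0.05 — is the substance; it is applied to relative
abundances with a pseudocount ε (default: half the smallest nonzero
relative abundance in the table), fold change (mean RA_B + ε)/(mean
RA_A + ε), and p from Welch's t on log(RA + ε). The test is a documented,
swappable component; absolute differential-OTU counts from count-model
pipelines on real data are not expected to be reproduced, and the
fold-change definition on relative abundance (rather than normalised
counts) is a stated choice.

## Guild assignment

Matching is exact (case-insensitive) on taxon names after rank-prefix
stripping, searching each lineage from species up to phylum; the most
specific database hit wins; duplicates at one (taxon, level) resolve
last-wins with a warning. No fuzzy matching. The bundled
`guild_fixture.tsv` is a small curated reference (~40 taxa of common
soil fungi with FUNGuild-compatible columns), built for testing and the
synthetic pipeline — it is not the FUNGuild database, and a full export
with the same columns can be supplied instead.

For trophic-mode summaries an OTU's relative abundance is split equally
across the modes named in a composite guild (e.g. Pathotroph-Saprotroph
contributes half to each); published summaries do not state how composite
guilds were counted, so the split rule is a documented choice that
conserves total abundance.

## Co-occurrence networks

Construction: retain OTUs with mean relative abundance ≥ 0.02%, ranked by
mean relative abundance, truncated to the top 400 (boundary ties break
lexicographically by OTU id); all-pairs Spearman ρ with midrank ties;
two-sided p from the t approximation (|ρ| = 1 → p = 0; constant rows →
ρ = 0, p = 1 with a warning); edges at |ρ| > 0.6 **and** p < 0.05
(strict inequalities); no multiple-testing correction on edge p-values by
default (a BH option exists via `bh_fdr`), matching the conventional raw
p < 0.05 rule. Isolated OTUs are dropped, which is why published node
counts (371/372/366) fall below the 400 filtered OTUs. The "≥ 0.02% in
each sample" phrasing common in methods sections is read as a *mean*
relative-abundance threshold; the per-sample-in-every-sample reading
would be far more restrictive, and the threshold is configurable.

Topology panel conventions:

* "Number of clusters" = connected components (published values of 67–75
  on ~370-node sparse graphs are consistent with components, not
  modules); module counts are available separately from the partition.
* Centralization is Freeman's degree centralization; the normalization
  is unstated in most papers, Freeman is the default choice.
* Community detection is Louvain (resolution 1) on the **unsigned,
  unweighted** graph, best Q over 10 seeded restarts; signed-modularity
  variants are out of scope.
* The modularity null is Erdős–Rényi G(n, m) with the observed node and
  edge counts (default 100 replicates, mean ± sd); degree-preserving
  rewiring is not currently offered.
* Relative modularity = (Q − Q_rand)/Q_rand. The published values are
  also consistent with the plain ratio Q/Q_rand; no formula is ever
  printed in the literature, so the difference-ratio is the package's
  stated convention and the plain ratio is trivially available.
* Null-modularity magnitudes are algorithm-dependent: Louvain finds
  Q ≈ 0.38 on G(371, 1154) where greedier detectors report ≈ 0.31.
  Comparisons of Q_rand across tools are therefore not meaningful, and
  the package only ever contrasts Q with Q_rand computed by the *same*
  detector.

Module similarity between two networks: Jaccard overlap of module member
sets over shared OTU ids; the reported count is the maximum number of
one-to-one module pairs with Jaccard ≥ 0.3 (maximum bipartite matching —
a greedy descending-Jaccard pass can undercount this by pairing a module
with its best partner when a one-step-worse assignment frees a second
match).

## Robustness

Natural connectivity λ̄ = ln((1/n) Σ e^{λᵢ}) is computed by symmetric
eigendecomposition with a log-sum-exp reduction, so large graphs do not
overflow. Attack curves remove a growing fraction of nodes (default step
0.05 up to 0.8, at least one node always kept), either uniformly at
random (default 100 replicates, averaged) or in descending intact-graph
degree with id tie-breaks (deterministic). Published robustness figures
rarely state strategy, steps or replication; these defaults are the
package's own and are recorded in every output.

"Community stability" contrasts between groups are not standardised
anywhere; the package implements a defined substitute and labels it as
such: the mean between-group Bray–Curtis dissimilarity per group pair,
with a within-group bootstrap (resample samples with replacement, default
1000 reps) for a 95% percentile interval.

## Synthetic communities

The generator emulates the features of a three-stand × five-timepoint
soil fungal survey that the analyses rely on:

* **Group phylum profiles** (FN/SN/TN): Ascomycota 72.9/69.7/57.9%,
  Mucoromycota 14.8/13.8/18.9%, Basidiomycota 6.5/10.8/11.6%, remainder
  unclassified — the composition regime of temperate forest soils under
  stand conversion.
* **Seasonal trophic modes**: saprotroph share 0.71/0.58/0.62/0.70/0.74
  across T901/T904/T907/T910/T001 (elevated in autumn/winter, within the
  66–76% range reported for such soils), symbiotrophs peaking in spring
  (7.3% at T904 vs 1–2% otherwise), pathotrophs flat at 10%.
* **Depths** uniform on 30,000–50,000 reads, echoing per-sample averages
  of ITS surveys at this scale.
* **Planted correlation blocks**: members share a latent Gaussian factor
  (pairwise latent correlation ρ, sign pattern ±) transformed
  monotonically into abundance space. Spearman's ρ is invariant to
  monotone transforms, so the latent ρ is the rank-correlation target; a
  Gaussian copula at ρ = 0.9 yields pair Spearman ≈ (6/π)·asin(ρ/2) ≈
  0.88 before count noise. Defaults: three blocks of 10 OTUs at
  ρ = 0.9, one with a mixed sign pattern.
* **Counts**: Dirichlet-multinomial around the per-sample expected
  composition (concentration 5000 by default) after log-normal
  perturbation (σ = 1.0).

Design choices that matter and why:

* *Replication*: three replicates per (group, timepoint) cell by default
  (45 samples), so group tests and per-group networks (15 samples) are
  well-posed; surveys that pool to one sample per cell can be emulated
  with `samples_per_cell=1`.
* *Blocks are taxonomically and functionally coherent* (one phylum, one
  trophic mode per block), as observed network modules tend to be; this
  also prevents group-level phylum factors from decorrelating block
  members across pooled samples.
* *Block abundance*: block members' base weights are drawn around a ×6
  boost with half the community's log-spread, placing them in the
  abundant fraction. Planted correlations among rare OTUs are not
  recoverable at |ρ| > 0.6 — count noise dominates — and the generator
  is explicit about that regime choice.
* *Margin calibration*: log-normal perturbation followed by closure
  biases mean realized shares toward heavy-tailed dominant taxa, so the
  per-cell expected composition is calibrated against a fixed Monte-Carlo
  panel of the noise (400 draws, 4 iterations) until *realized* phylum
  and trophic-mode margins hit the targets. Without this step, realized
  dominant-phylum shares overshoot targets by ~4 percentage points.
* *Overdispersion default* (concentration 5000) is milder than fitted
  values for many real surveys (often 20–200). The generator's role is a
  ground-truth testbed: at heavy overdispersion the planted rank signal
  is provably swamped for all but the most abundant taxa, which would
  test the noise, not the method. The concentration is a template field;
  heavier regimes are one assignment away.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: taxonomy-assignment error, chimeras and other
upstream artifacts; phylogenetic correlation structure beyond the planted
blocks; compositional effects of a few extremely dominant OTUs beyond the
log-normal tail; true fold-change distributions of differential OTUs.
Absolute published quantities that depend on the real sequencing data
(OTU totals, exact differential-OTU counts, the exact networks) are out
of reach by construction; what is validated is the machinery — exact
identities, closed forms, calibration, and recovery of planted structure.

## Numerical conventions

Permutation p-values use the +1 correction. Seeds are explicit
everywhere; the pipeline refuses to run without one per stochastic stage,
and identical configs produce byte-identical numeric outputs. Eigenvalue
positivity in PCoA uses a spectral-norm-relative tolerance of 1e-10.
Spearman ρ is clipped to [−1, 1] before the t transform. Degenerate
inputs (constant OTUs, empty networks, single-sample groups) warn or
raise as documented per function rather than silently propagating NaNs.

## Limitations

* Per-stand networks from 15 samples sit near the detection floor of the
  |ρ| > 0.6 rule (null sd of Spearman ≈ 0.27 at n = 15), so a large
  share of their edges are threshold noise; pooled-sample networks are
  the reliable recovery setting, and the acceptance checks use them.
* The ER null ignores degree heterogeneity; relative modularity against
  a degree-preserving null would be lower for hub-heavy networks.
* Guild assignment is only as good as the reference; the bundled fixture
  is intentionally small.
* PLS-DA and figure rendering are out of scope; outputs are coordinates
  and tables.
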