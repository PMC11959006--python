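"""Synthetic soil-fungal OTU tables with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume for a three-stand (FN/SN/TN), five-timepoint sampling design:

* group-specific phylum composition (Ascomycota-dominated, with
  group-level shifts toward Basidiomycota and unclassified taxa),
* seasonally varying trophic-mode proportions (saprotrophs elevated in
  autumn/winter, symbiotrophs peaking in spring),
* uneven sequencing depth per sample, and
* planted inter-OTU correlation blocks: members of a block share a latent
  Gaussian factor, transformed monotonically into abundance space, so the
  pairwise rank correlation is controlled by the block's latent ρ and its
  sign pattern.  Spearman's ρ is invariant to monotone transforms, which
  is what makes the copula coupling a usable ground truth for network
  recovery.

Counts are Dirichlet-multinomial around the per-sample expected
composition, giving realistic overdispersion relative to a plain
multinomial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .tables import (OTUTable, SampleMetadata, TaxonomyLineage,
                     UNCLASSIFIED, aggregate_by_rank, relative_abundance)

GROUPS = ("FN", "SN", "TN")
TIMEPOINTS = ("T901", "T904", "T907", "T910", "T001")

# class/genus pools per (phylum, trophic mode); genera resolve against the
# bundled guild fixture so planted modes survive the assignment step
_GENUS_POOL = {
    ("Ascomycota", "Saprotroph"): [
        ("Eurotiomycetes", "Penicillium"), ("Eurotiomycetes", "Aspergillus"),
        ("Sordariomycetes", "Chaetomium"), ("Eurotiomycetes", "Talaromyces"),
    ],
    ("Ascomycota", "Pathotroph"): [
        ("Sordariomycetes", "Verticillium"), ("Dothideomycetes", "Alternaria"),
        ("Leotiomycetes", "Botrytis"),
    ],
    ("Ascomycota", "Symbiotroph"): [
        ("Pezizomycetes", "Tuber"), ("Dothideomycetes", "Cenococcum"),
        ("Leotiomycetes", "Oidiodendron"),
    ],
    ("Basidiomycota", "Saprotroph"): [
        ("Agaricomycetes", "Coprinellus"), ("Agaricomycetes", "Trametes"),
        ("Tremellomycetes", "Trichosporon"), ("Agaricomycetes", "Mycena"),
    ],
    ("Basidiomycota", "Symbiotroph"): [
        ("Agaricomycetes", "Russula"), ("Agaricomycetes", "Inocybe"),
        ("Agaricomycetes", "Laccaria"), ("Agaricomycetes", "Tomentella"),
    ],
    ("Basidiomycota", "Pathotroph"): [
        ("Pucciniomycetes", "Puccinia"), ("Ustilaginomycetes", "Ustilago"),
        ("Exobasidiomycetes", "Exobasidium"),
    ],
    ("Mucoromycota", "Saprotroph"): [
        ("Mortierellomycetes", "Mortierella"), ("Mucoromycetes", "Mucor"),
        ("Umbelopsidomycetes", "Umbelopsis"), ("Mucoromycetes", "Rhizopus"),
    ],
    ("Mucoromycota", "Symbiotroph"): [
        ("Endogonomycetes", "Endogone"), ("Endogonomycetes", "Jimgerdemannia"),
    ],
    ("Mucoromycota", "Pathotroph"): [("Mucoromycetes", "Choanephora")],
}
# class-only lineages for OTUs left without a planted trophic mode; these
# classes have no record in the bundled guild fixture, so the OTUs come out
# "Undefined" after assignment, as planted
_UNDEFINED_CLASSES = {
    "Ascomycota": ["Sordariomycetes", "Dothideomycetes"],
    "Basidiomycota": ["Tremellomycetes"],
}
_MODES = ("Saprotroph", "Symbiotroph", "Pathotroph")
_UNDEF_MODE = "Undefined"


@dataclass
class CorrelationBlock:
    """A set of OTU indices coupled through one latent factor."""

    members: list[int]
    rho_latent: float
    signs: list[int] = field(default_factory=list)  # +1/−1 per member

    def __post_init__(self):
        if not (0.0 < self.rho_latent < 1.0):
            raise ValueError("rho_latent must lie in (0, 1)")
        if not self.signs:
            self.signs = [1] * len(self.members)
        if len(self.signs) != len(self.members):
            raise ValueError("one sign per member required")
        if any(s not in (-1, 1) for s in self.signs):
            raise ValueError("signs must be ±1")


@dataclass
class CommunityTemplate:
    groups: tuple[str, ...] = GROUPS
    timepoints: tuple[str, ...] = TIMEPOINTS
    n_otus: int = 500
    phylum_profile: dict = field(default_factory=dict)   # group → {phylum: prop}
    guild_profile: dict = field(default_factory=dict)    # mode → {timepoint: prop}
    depth_range: tuple[int, int] = (30_000, 50_000)
    correlation_blocks: list[CorrelationBlock] = field(default_factory=list)
    overdispersion: float = 5000.0   # Dirichlet concentration
    base_sigma: float = 1.5          # log-sd of fixed OTU base weights
    sample_sigma: float = 1.0        # log-sd of per-sample abundance noise
    block_boost: float = 6.0         # base-weight scale for block OTUs
    seed: int = 0

    def __post_init__(self):
        self.correlation_blocks = [
            b if isinstance(b, CorrelationBlock) else CorrelationBlock(**b)
            for b in self.correlation_blocks
        ]
        for g, prof in self.phylum_profile.items():
            if sum(prof.values()) > 1.0 + 1e-9:
                raise ValueError(f"phylum proportions for {g} exceed 1")
        seen: set[int] = set()
        for b in self.correlation_blocks:
            if seen & set(b.members):
                raise ValueError("correlation blocks must be disjoint")
            seen |= set(b.members)
            if max(b.members, default=-1) >= self.n_otus:
                raise ValueError("block member index beyond n_otus")
        if self.n_otus < len(seen):
            raise ValueError("n_otus smaller than total block membership")

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["groups"] = list(self.groups)
        doc["timepoints"] = list(self.timepoints)
        doc["depth_range"] = list(self.depth_range)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CommunityTemplate":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc["groups"] = tuple(doc["groups"])
        doc["timepoints"] = tuple(doc["timepoints"])
        doc["depth_range"] = tuple(doc["depth_range"])
        doc["correlation_blocks"] = [
            CorrelationBlock(**b) for b in doc.get("correlation_blocks", [])
        ]
        return cls(**doc)


@dataclass
class PlantedStructure:
    """Ground truth for network recovery: which OTU pairs were coupled."""

    otu_ids: list[str]
    adjacency: np.ndarray  # symmetric bool, zero diagonal
    signs: np.ndarray      # +1/−1 where adjacency, else 0

    def __post_init__(self):
        a = np.asarray(self.adjacency, dtype=bool)
        if not (a == a.T).all() or a.diagonal().any():
            raise ValueError("adjacency must be symmetric with zero diagonal")
        self.adjacency = a
        self.signs = np.asarray(self.signs, dtype=int)

    def pairs(self) -> list[tuple[str, str, int]]:
        out = []
        iu = np.triu_indices_from(self.adjacency, k=1)
        for i, j in zip(*iu):
            if self.adjacency[i, j]:
                out.append((self.otu_ids[i], self.otu_ids[j],
                            int(self.signs[i, j])))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs(), columns=["source", "target", "sign"])


def default_template(seed: int = 0) -> CommunityTemplate:
    """The default study conditions: three stands × five timepoints.

    Phylum targets are the observed group means of an Ascomycota-dominated
    temperate forest soil community (FN/SN/TN: Ascomycota 72.9/69.7/57.9%,
    Mucoromycota 14.8/13.8/18.9%, Basidiomycota 6.5/10.8/11.6%, remainder
    unclassified).  Saprotroph share is elevated at the autumn/winter
    timepoints (T901, T910, T001) and symbiotrophs peak in spring (T904).
    Three correlation blocks of ten OTUs each are planted at latent ρ = 0.9,
    two all-positive and one with a mixed sign pattern.
    """
    phylum_profile = {
        "FN": {"Ascomycota": 0.729, "Mucoromycota": 0.148, "Basidiomycota": 0.065},
        "SN": {"Ascomycota": 0.697, "Mucoromycota": 0.138, "Basidiomycota": 0.108},
        "TN": {"Ascomycota": 0.579, "Mucoromycota": 0.189, "Basidiomycota": 0.116},
    }
    guild_profile = {
        "Saprotroph": {"T901": 0.71, "T904": 0.58, "T907": 0.62,
                       "T910": 0.70, "T001": 0.74},
        "Symbiotroph": {"T901": 0.018, "T904": 0.073, "T907": 0.020,
                        "T910": 0.015, "T001": 0.013},
        "Pathotroph": {"T901": 0.10, "T904": 0.10, "T907": 0.10,
                       "T910": 0.10, "T001": 0.10},
    }
    blocks = [
        CorrelationBlock(members=list(range(0, 10)), rho_latent=0.9),
        CorrelationBlock(members=list(range(10, 20)), rho_latent=0.9),
        CorrelationBlock(members=list(range(20, 30)), rho_latent=0.9,
                         signs=[1] * 5 + [-1] * 5),
    ]
    return CommunityTemplate(
        phylum_profile=phylum_profile, guild_profile=guild_profile,
        correlation_blocks=blocks, seed=seed,
    )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _draw_community(template: CommunityTemplate, rng: np.random.Generator):
    """Fixed per-simulation OTU attributes: phylum, mode, lineage, weight."""
    n = template.n_otus
    phyla = sorted({p for prof in template.phylum_profile.values() for p in prof})
    mean_phy = np.array([
        np.mean([template.phylum_profile[g].get(p, 0.0)
                 for g in template.groups]) for p in phyla
    ])
    probs = np.append(mean_phy, max(1.0 - mean_phy.sum(), 0.0))
    probs /= probs.sum()
    otu_phyla = rng.choice(phyla + [UNCLASSIFIED], size=n, p=probs)

    mean_mode = np.array([
        np.mean(list(template.guild_profile.get(m, {"_": 0.0}).values()))
        for m in _MODES
    ])
    mode_probs = np.append(mean_mode, max(1.0 - mean_mode.sum(), 0.0))
    mode_probs /= mode_probs.sum()
    otu_modes = rng.choice(list(_MODES) + [_UNDEF_MODE], size=n, p=mode_probs)
    # the guild fixture carries a phylum-level Mucoromycota record, so a
    # class-only Mucoromycota OTU could never come out Undefined; keep the
    # planted Undefined pool in the other phyla
    otu_modes[(otu_phyla == "Mucoromycota") & (otu_modes == _UNDEF_MODE)] = "Saprotroph"
    otu_modes[otu_phyla == UNCLASSIFIED] = _UNDEF_MODE

    taxonomy = {}
    otu_ids = [f"OTU_{i + 1:04d}" for i in range(n)]
    for i, (ph, mode) in enumerate(zip(otu_phyla, otu_modes)):
        if ph == UNCLASSIFIED:
            taxonomy[otu_ids[i]] = TaxonomyLineage((("kingdom", "Fungi"),))
        elif mode == _UNDEF_MODE:
            classes = _UNDEFINED_CLASSES.get(ph, [None])
            cls = classes[int(rng.integers(len(classes)))]
            pairs = (("kingdom", "Fungi"), ("phylum", ph))
            if cls is not None:
                pairs += (("class", cls),)
            taxonomy[otu_ids[i]] = TaxonomyLineage(pairs)
        else:
            pool = _GENUS_POOL[(ph, mode)]
            cls, genus = pool[int(rng.integers(len(pool)))]
            taxonomy[otu_ids[i]] = TaxonomyLineage((
                ("kingdom", "Fungi"), ("phylum", ph), ("class", cls),
                ("genus", genus),
            ))

    # correlation blocks are taxonomically and functionally coherent, the
    # way observed network modules tend to be: one phylum and one trophic
    # mode per block, and weights in the abundant fraction so the planted
    # signal is not drowned by count noise
    block_phyla = ["Ascomycota", "Basidiomycota", "Mucoromycota"]
    for k, b in enumerate(template.correlation_blocks):
        ph = block_phyla[k % len(block_phyla)]
        mode = "Saprotroph" if k % 2 == 0 else "Symbiotroph"
        pool = _GENUS_POOL[(ph, mode)]
        for i in b.members:
            otu_phyla[i] = ph
            otu_modes[i] = mode
            cls, genus = pool[int(rng.integers(len(pool)))]
            taxonomy[otu_ids[i]] = TaxonomyLineage((
                ("kingdom", "Fungi"), ("phylum", ph), ("class", cls),
                ("genus", genus),
            ))

    weights = np.exp(template.base_sigma * rng.standard_normal(n))
    for b in template.correlation_blocks:
        weights[b.members] = template.block_boost * np.exp(
            0.5 * template.base_sigma
            * rng.standard_normal(len(b.members)))
    return otu_ids, otu_phyla, otu_modes, taxonomy, weights


def _margin_targets(template, group, timepoint):
    phyla = sorted({p for prof in template.phylum_profile.values() for p in prof})
    phy_target = {p: template.phylum_profile[group].get(p, 0.0) for p in phyla}
    phy_target[UNCLASSIFIED] = max(1.0 - sum(phy_target.values()), 0.0)
    mode_target = {m: template.guild_profile[m][timepoint]
                   for m in _MODES if m in template.guild_profile}
    mode_target[_UNDEF_MODE] = max(1.0 - sum(mode_target.values()), 0.0)
    return phy_target, mode_target


def _calibrate_composition(p, otu_phyla, otu_modes, phy_target, mode_target,
                           noise, n_iter: int = 4) -> np.ndarray:
    """Adjust base proportions so *realized* margins hit the targets.

    Log-normal perturbation followed by closure (renormalisation) biases
    mean realized shares toward the heavy-tailed dominant taxa, so margins
    are matched on a fixed Monte-Carlo panel of the per-sample noise
    (``noise``: draws × OTUs of exp(σz) factors, block coupling included)
    rather than on the noise-free proportions.
    """
    for _ in range(n_iter):
        x = p * noise
        realized = (x / x.sum(axis=1, keepdims=True)).mean(axis=0)
        for attr, target in ((otu_modes, mode_target), (otu_phyla, phy_target)):
            for label, share in target.items():
                mask = attr == label
                cur = realized[mask].sum()
                if cur > 0 and share > 0:
                    p[mask] *= share / cur
        p = p / p.sum()
    return p


def _expected_composition(template, otu_phyla, otu_modes, weights,
                          group, timepoint, n_iter: int = 8) -> np.ndarray:
    """Expected OTU proportions for one (group, timepoint) cell.

    Iterative proportional fitting of multiplicative phylum and mode
    factors onto the fixed OTU base weights.
    """
    phy_target, mode_target = _margin_targets(template, group, timepoint)

    p = weights / weights.sum()
    for _ in range(n_iter):
        for attr, target in ((otu_modes, mode_target), (otu_phyla, phy_target)):
            for label, share in target.items():
                mask = attr == label
                cur = p[mask].sum()
                if cur > 0 and share > 0:
                    p[mask] *= share / cur
            p = p / p.sum()
    return p


def simulate_counts(
    template: CommunityTemplate, samples_per_cell: int = 3, seed: int = 0
) -> tuple[OTUTable, PlantedStructure]:
    """Draw an OTU table from the template; returns the planted ground truth.

    Per sample: depth uniform over ``depth_range``; latent Gaussians give
    block members a shared factor (copula coupling); expected proportions
    are perturbed log-normally and counts drawn Dirichlet-multinomial with
    the template's concentration.  Deterministic given (template.seed, seed).
    """
    if samples_per_cell < 1:
        raise ValueError("samples_per_cell must be at least 1")
    rng = np.random.default_rng([template.seed, seed])
    otu_ids, otu_phyla, otu_modes, taxonomy, weights = _draw_community(template, rng)
    n = template.n_otus

    # fixed noise panel for margin calibration (see _calibrate_composition)
    cal_rng = np.random.default_rng([template.seed, seed, 7919])
    k_cal = 400
    zc = cal_rng.standard_normal((k_cal, n))
    for b in template.correlation_blocks:
        f = cal_rng.standard_normal((k_cal, 1))
        s = np.asarray(b.signs, dtype=float)
        zc[:, b.members] = s * (np.sqrt(b.rho_latent) * f
                                + np.sqrt(1.0 - b.rho_latent) * zc[:, b.members])
    noise = np.exp(template.sample_sigma * zc)

    expected = {}
    for g in template.groups:
        for t in template.timepoints:
            p0 = _expected_composition(template, otu_phyla, otu_modes,
                                       weights, g, t)
            phy_t, mode_t = _margin_targets(template, g, t)
            expected[(g, t)] = _calibrate_composition(
                p0, otu_phyla, otu_modes, phy_t, mode_t, noise)

    cols, metadata = [], []
    counts = []
    lo, hi = template.depth_range
    for g in template.groups:
        for t in template.timepoints:
            for r in range(samples_per_cell):
                sid = f"{g}_{t}_{r + 1}"
                cols.append(sid)
                metadata.append(SampleMetadata(sid, g, t))
                depth = int(rng.integers(lo, hi + 1))
                z = rng.standard_normal(n)
                for b in template.correlation_blocks:
                    f = rng.standard_normal()
                    s = np.asarray(b.signs, dtype=float)
                    z[b.members] = s * (np.sqrt(b.rho_latent) * f
                                        + np.sqrt(1.0 - b.rho_latent)
                                        * z[b.members])
                x = expected[(g, t)] * np.exp(template.sample_sigma * z)
                alpha = np.maximum(template.overdispersion * x / x.sum(), 1e-8)
                pi = rng.dirichlet(alpha)
                counts.append(rng.multinomial(depth, pi))

    frame = pd.DataFrame(np.array(counts).T, index=otu_ids, columns=cols)
    # a zero-total sample is astronomically unlikely at these depths, but
    # the OTUTable invariant requires positive depth
    table = OTUTable(frame, taxonomy, metadata)

    adjacency = np.zeros((n, n), dtype=bool)
    signs = np.zeros((n, n), dtype=int)
    for b in template.correlation_blocks:
        for ii, i in enumerate(b.members):
            for jj, j in enumerate(b.members):
                if i != j:
                    adjacency[i, j] = True
                    signs[i, j] = b.signs[ii] * b.signs[jj]
    return table, PlantedStructure(otu_ids, adjacency, signs)


def phylum_composition_check(
    table: OTUTable, template: CommunityTemplate, tol: float = 0.05
) -> pd.DataFrame:
    """Realized vs. target mean phylum relative abundance per group.

    Returns one row per (group, phylum) with the absolute deviation and a
    flag where it exceeds ``tol``.
    """
    agg = aggregate_by_rank(table, "phylum")
    ra = relative_abundance(agg)
    meta = table.metadata_frame()
    rows = []
    for g in template.groups:
        samples = meta.index[meta["group"] == g]
        realized = ra[samples].mean(axis=1)
        for ph, target in template.phylum_profile[g].items():
            obs = float(realized.get(ph, 0.0))
            rows.append({
                "group": g, "phylum": ph, "target": target, "realized": obs,
                "deviation": abs(obs - target), "flagged": abs(obs - target) > tol,
            })
    return pd.DataFrame(rows)
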