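"""OTU count tables: I/O, rarefaction, and composition-level summaries.

The central object is :class:`OTUTable`, an integer OTU × sample count
matrix carrying a taxonomy lineage per OTU and a metadata record (group,
timepoint) per sample.  Everything downstream — diversity, differential
composition, guild assignment, co-occurrence networks — consumes this one
container.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIXES = {r: f"{r[0]}__" for r in RANKS}
_RANK_PREFIXES["class"] = "c__"
_PREFIX_TO_RANK = {v: k for k, v in _RANK_PREFIXES.items()}

UNCLASSIFIED = "Unclassified"


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


@dataclass(frozen=True)
class TaxonomyLineage:
    """Ordered rank → taxon-name map; any suffix of ranks may be absent."""

    ranks: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        seen = [r for r, _ in self.ranks]
        order = [r for r in RANKS if r in seen]
        if seen != order:
            raise ValueError(f"ranks out of canonical order: {seen}")
        for r, name in self.ranks:
            if not name:
                raise ValueError(f"empty taxon name at rank {r}")

    def get(self, rank: str) -> str | None:
        for r, name in self.ranks:
            if r == rank:
                return name
        return None

    def as_dict(self) -> dict[str, str]:
        return dict(self.ranks)

    @classmethod
    def from_string(cls, lineage: str) -> "TaxonomyLineage":
        """Parse a semicolon-delimited, rank-prefixed lineage string.

        ``k__Fungi;p__Ascomycota;c__Sordariomycetes`` → lineage with
        kingdom/phylum/class set.  Empty fields (``g__``) and the literal
        "unclassified"/"unidentified" markers terminate the lineage.
        """
        pairs: list[tuple[str, str]] = []
        for token in lineage.split(";"):
            token = token.strip()
            if not token:
                continue
            prefix, _, name = token.partition("__")
            rank = _PREFIX_TO_RANK.get(prefix + "__")
            if rank is None:
                raise FormatError(f"unknown rank prefix in {token!r}")
            name = name.strip()
            if not name or name.lower() in {"unclassified", "unidentified", "norank"}:
                break
            pairs.append((rank, name))
        return cls(tuple(pairs))

    def to_string(self) -> str:
        return ";".join(f"{_RANK_PREFIXES[r]}{n}" for r, n in self.ranks)


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    group: str
    timepoint: str

    def __post_init__(self):
        if not self.sample_id or not self.group or not self.timepoint:
            raise ValueError("sample_id, group and timepoint must be non-empty")


@dataclass
class OTUTable:
    """Integer count matrix (rows = OTUs, columns = samples) with annotations.

    Parameters
    ----------
    counts : DataFrame
        Non-negative integer counts, index = OTU ids, columns = sample ids.
    taxonomy : mapping OTU id → TaxonomyLineage
        Every row must have an entry (possibly a fully unclassified lineage).
    metadata : list of SampleMetadata
        One record per column, order-aligned is not required; matched by id.
    """

    counts: pd.DataFrame
    taxonomy: dict[str, TaxonomyLineage] = field(default_factory=dict)
    metadata: list[SampleMetadata] = field(default_factory=list)

    def __post_init__(self):
        self.counts = self.counts.astype(np.int64, copy=False)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup}")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate OTU id: {dup}")
        if not self.taxonomy:
            self.taxonomy = {o: TaxonomyLineage() for o in self.counts.index}
        missing = set(self.counts.index) - set(self.taxonomy)
        if missing:
            raise ValueError(f"OTUs without taxonomy: {sorted(missing)[:5]}")
        if not self.metadata:
            self.metadata = [
                SampleMetadata(s, "NA", "NA") for s in self.counts.columns
            ]
        meta_ids = [m.sample_id for m in self.metadata]
        if len(set(meta_ids)) != len(meta_ids):
            raise ValueError("duplicate sample id in metadata")
        missing = set(self.counts.columns) - set(meta_ids)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        depths = self.counts.sum(axis=0)
        if (depths <= 0).any():
            empty = depths.index[depths <= 0][0]
            raise ValueError(f"sample {empty} has zero total count")

    # -- convenience -------------------------------------------------------
    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def depths(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def metadata_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [(m.sample_id, m.group, m.timepoint) for m in self.metadata],
            columns=["sample_id", "group", "timepoint"],
        ).set_index("sample_id")
        return df.loc[self.counts.columns]

    def group_map(self) -> dict[str, str]:
        return {m.sample_id: m.group for m in self.metadata}

    def subset_samples(self, sample_ids: Iterable[str]) -> "OTUTable":
        ids = list(sample_ids)
        meta = [m for m in self.metadata if m.sample_id in set(ids)]
        return OTUTable(self.counts[ids].copy(), dict(self.taxonomy), meta)

    def subset_otus(self, otu_ids: Iterable[str]) -> "OTUTable":
        ids = list(otu_ids)
        tax = {o: self.taxonomy[o] for o in ids}
        return OTUTable(self.counts.loc[ids].copy(), tax, list(self.metadata))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_otu_table(path, format: str = "tsv") -> OTUTable:
    """Read an OTU table from TSV (QIIME-classic layout) or BIOM v1 JSON.

    The TSV dialect has an ``#OTU ID`` column, one integer column per
    sample, and a trailing ``taxonomy`` column with semicolon-delimited,
    rank-prefixed lineages.
    """
    if format == "tsv":
        return _read_tsv(path)
    if format == "biom-json":
        return _read_biom_json(path)
    raise ValueError(f"unknown format {format!r}")


def _read_tsv(path) -> OTUTable:
    df = pd.read_csv(path, sep="\t", comment=None, dtype=str)
    df.columns = [c.lstrip("#").strip() if i == 0 else c for i, c in enumerate(df.columns)]
    if df.columns[0] not in {"OTU ID", "OTU_ID", "otu_id"}:
        raise FormatError(f"first column must be an OTU-id column, got {df.columns[0]!r}")
    tax_col = next((c for c in df.columns if c.lower() == "taxonomy"), None)
    if tax_col is None:
        raise FormatError("missing taxonomy column")
    otu_ids = df.iloc[:, 0].tolist()
    taxonomy = {
        o: TaxonomyLineage.from_string(t if isinstance(t, str) else "")
        for o, t in zip(otu_ids, df[tax_col])
    }
    sample_cols = [c for c in df.columns[1:] if c != tax_col]
    counts = df[sample_cols].copy()
    for c in sample_cols:
        col = pd.to_numeric(counts[c], errors="coerce")
        if col.isna().any():
            bad = counts[c][col.isna()].iloc[0]
            raise ValueError(f"non-numeric count {bad!r} in sample {c}")
        if (col < 0).any():
            raise ValueError(f"negative count in sample {c}")
        if (col % 1 != 0).any():
            raise ValueError(f"non-integer count in sample {c}")
        counts[c] = col.astype(np.int64)
    counts.index = pd.Index(otu_ids, name="OTU ID")
    return OTUTable(counts, taxonomy)


def _read_biom_json(path) -> OTUTable:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        otu_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        shape = tuple(doc["shape"])
    except (KeyError, TypeError) as exc:
        raise FormatError(f"not a BIOM v1 JSON table: {exc}") from exc
    mat = np.zeros(shape, dtype=np.int64)
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[i, j] = int(v)
    else:
        mat[:] = np.asarray(doc["data"], dtype=np.int64)
    taxonomy = {}
    for r in doc["rows"]:
        md = r.get("metadata") or {}
        tax = md.get("taxonomy", "")
        if isinstance(tax, list):
            tax = ";".join(tax)
        taxonomy[r["id"]] = TaxonomyLineage.from_string(tax)
    counts = pd.DataFrame(mat, index=otu_ids, columns=sample_ids)
    return OTUTable(counts, taxonomy)


def write_otu_table(table: OTUTable, path) -> None:
    """Write the TSV dialect read by :func:`read_otu_table` (bit-exact)."""
    out = table.counts.copy()
    out.insert(len(out.columns), "taxonomy",
               [table.taxonomy[o].to_string() for o in out.index])
    out.index.name = "#OTU ID"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> list[SampleMetadata]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "timepoint"}
    if not required.issubset(df.columns):
        raise FormatError(f"metadata needs columns {sorted(required)}")
    return [SampleMetadata(r.sample_id, r.group, r.timepoint)
            for r in df.itertuples()]


def write_metadata(metadata: list[SampleMetadata], path) -> None:
    pd.DataFrame(
        [(m.sample_id, m.group, m.timepoint) for m in metadata],
        columns=["sample_id", "group", "timepoint"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Normalisation and composition summaries
# ---------------------------------------------------------------------------

def rarefy(table: OTUTable, depth: int, seed: int) -> OTUTable:
    """Subsample each sample to ``depth`` reads without replacement.

    Deterministic given ``seed``.  The multivariate hypergeometric draw is
    exactly "pick ``depth`` of the sample's reads uniformly at random".
    """
    depth = int(depth)
    if depth <= 0:
        raise ValueError("depth must be positive")
    depths = table.depths()
    low = depths[depths < depth]
    if len(low):
        raise ValueError(
            f"depth {depth} exceeds total count of sample {low.index[0]} ({low.iloc[0]})"
        )
    rng = np.random.default_rng(seed)
    out = np.empty(table.counts.shape, dtype=np.int64)
    arr = table.counts.to_numpy()
    for j in range(arr.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(arr[:, j], depth)
    counts = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return OTUTable(counts, dict(table.taxonomy), list(table.metadata))


def relative_abundance(table: OTUTable) -> pd.DataFrame:
    """Per-sample proportions; every column sums to 1."""
    return table.counts / table.counts.sum(axis=0)


def aggregate_by_rank(table: OTUTable, rank: str) -> OTUTable:
    """Sum counts of OTUs sharing a taxon at ``rank``; unresolved OTUs pool
    into a single "Unclassified" row.  Per-sample totals are conserved."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    labels = [table.taxonomy[o].get(rank) or UNCLASSIFIED for o in table.otu_ids]
    agg = table.counts.groupby(pd.Index(labels, name=rank), sort=True).sum()
    # taxa keep only their lineage up to the aggregation rank
    tax = {}
    depth = RANKS.index(rank) + 1
    for o, lab in zip(table.otu_ids, labels):
        if lab not in tax:
            if lab == UNCLASSIFIED:
                tax[lab] = TaxonomyLineage()
            else:
                pairs = tuple(p for p in table.taxonomy[o].ranks
                              if RANKS.index(p[0]) < depth)
                tax[lab] = TaxonomyLineage(pairs)
    return OTUTable(agg, tax, list(table.metadata))


def goods_coverage(table: OTUTable) -> pd.Series:
    """Good's coverage 1 − F1/N per sample (F1 = singleton OTUs)."""
    arr = table.counts.to_numpy()
    f1 = (arr == 1).sum(axis=0)
    n = arr.sum(axis=0)
    return pd.Series(1.0 - f1 / n, index=table.counts.columns, name="goods_coverage")


def shared_unique_counts(
    table: OTUTable, grouping: Mapping[str, str] | None = None
) -> dict[frozenset, int]:
    """UpSet-style partition: for every non-empty subset of groups, the
    number of OTUs present (count > 0 in ≥1 sample) in exactly those groups.

    OTUs absent from every group are not counted, so the subset counts sum
    to the number of OTUs observed anywhere.
    """
    grouping = grouping or table.group_map()
    missing = [s for s in table.sample_ids if s not in grouping]
    if missing:
        raise ValueError(f"samples without a group label: {missing[:5]}")
    groups = sorted(set(grouping[s] for s in table.sample_ids))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    present = {}
    for g in groups:
        cols = [s for s in table.sample_ids if grouping[s] == g]
        present[g] = (table.counts[cols].sum(axis=1) > 0).to_numpy()
    result = {}
    for r in range(1, len(groups) + 1):
        for subset in combinations(groups, r):
            inside = np.logical_and.reduce([present[g] for g in subset])
            outside = np.logical_or.reduce(
                [present[g] for g in groups if g not in subset]
            ) if len(subset) < len(groups) else np.zeros(table.shape[0], bool)
            result[frozenset(subset)] = int((inside & ~outside).sum())
    return result


def ternary_coordinates(
    table: OTUTable,
    grouping: Mapping[str, str] | None = None,
    min_fraction: float = 0.001,
    top_n: int = 20,
) -> pd.DataFrame:
    """Per-OTU shares of mean relative abundance across exactly three groups.

    OTUs with overall mean relative abundance below ``min_fraction`` are
    excluded; the ``top`` flag marks the ``top_n`` most abundant retained
    OTUs.  Each emitted triple sums to 1.
    """
    grouping = grouping or table.group_map()
    groups = sorted(set(grouping[s] for s in table.sample_ids))
    if len(groups) != 3:
        raise ValueError(f"ternary coordinates need exactly 3 groups, got {len(groups)}")
    ra = relative_abundance(table)
    overall = ra.mean(axis=1)
    keep = overall >= min_fraction
    means = pd.DataFrame({
        g: ra[[s for s in table.sample_ids if grouping[s] == g]].mean(axis=1)
        for g in groups
    })
    means = means[keep]
    total = means.sum(axis=1)
    nonzero = total > 0
    coords = means[nonzero].div(total[nonzero], axis=0)
    coords["mean_ra"] = overall[coords.index]
    ranked = coords["mean_ra"].rank(ascending=False, method="first")
    coords["top"] = ranked <= top_n
    return coords
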