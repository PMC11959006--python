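"""Guild assignment by taxonomy matching, in the style of FUNGuild.

A guild reference table maps taxon names (defined at some rank) to an
ecological guild, a trophic mode (Saprotroph / Symbiotroph / Pathotroph,
possibly hyphen-joined composites) and a confidence ranking.  Each OTU's
lineage is searched from species up to phylum; the most specific matching
record wins.  Matching is exact (case-insensitive) on taxon names after
rank-prefix stripping — no fuzzy matching.

The repository bundles a small curated reference covering common soil
fungi; a user-supplied full FUNGuild export with the same columns is
accepted by :func:`load_guild_db`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .tables import RANKS, FormatError, OTUTable, relative_abundance

TROPHIC_MODES = ("Saprotroph", "Symbiotroph", "Pathotroph")
UNDEFINED = "Undefined"

_COLUMNS = ["taxon", "taxonomicLevel", "trophicMode", "guild", "confidenceRanking"]


@dataclass(frozen=True)
class GuildRecord:
    taxon: str
    level: str  # rank name the taxon is defined at
    trophic_mode: str  # e.g. "Saprotroph" or "Pathotroph-Saprotroph"
    guild: str
    confidence: str

    def __post_init__(self):
        if self.level not in RANKS:
            raise ValueError(f"unknown rank {self.level!r}")
        if not self.guild:
            raise ValueError("guild must be non-empty")
        for part in self.trophic_mode.split("-"):
            if part not in TROPHIC_MODES:
                raise ValueError(f"unknown trophic mode component {part!r}")

    def modes(self) -> list[str]:
        return self.trophic_mode.split("-")


@dataclass(frozen=True)
class GuildAssignment:
    otu_id: str
    matched_taxon: str
    matched_rank: str
    guild: str
    trophic_mode: str
    confidence: str
    assigned: bool

    @classmethod
    def unassigned(cls, otu_id: str) -> "GuildAssignment":
        return cls(otu_id, "", "", UNDEFINED, UNDEFINED, "", False)


def load_guild_db(path=None) -> list[GuildRecord]:
    """Load a guild reference TSV (FUNGuild-compatible columns).

    With no path, the bundled curated fixture is loaded.  Duplicate
    (taxon, level) pairs resolve last-wins with a warning.
    """
    if path is None:
        path = resources.files("fungalnet.data") / "guild_fixture.tsv"
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"guild db missing columns: {missing}")
    records: dict[tuple[str, str], GuildRecord] = {}
    for row in df.itertuples():
        try:
            rec = GuildRecord(
                taxon=row.taxon, level=row.taxonomicLevel,
                trophic_mode=row.trophicMode, guild=row.guild,
                confidence=row.confidenceRanking,
            )
        except ValueError as exc:
            raise FormatError(f"bad guild record for {row.taxon!r}: {exc}") from exc
        key = (rec.taxon.lower(), rec.level)
        if key in records:
            warnings.warn(f"duplicate guild record for {rec.taxon} at {rec.level}; "
                          "keeping the last one")
        records[key] = rec
    return list(records.values())


def write_guild_db(records: list[GuildRecord], path) -> None:
    pd.DataFrame(
        [(r.taxon, r.level, r.trophic_mode, r.guild, r.confidence) for r in records],
        columns=_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def assign_guilds(table: OTUTable, db: list[GuildRecord]) -> list[GuildAssignment]:
    """Match each OTU's lineage against the reference, most specific rank first."""
    index: dict[tuple[str, str], GuildRecord] = {
        (r.taxon.lower(), r.level): r for r in db
    }
    assignments = []
    for otu in table.otu_ids:
        lineage = table.taxonomy[otu]
        hit = None
        for rank in reversed(RANKS):  # species → kingdom
            name = lineage.get(rank)
            if name is None:
                continue
            rec = index.get((name.lower(), rank))
            if rec is not None:
                hit = rec
                break
        if hit is None:
            assignments.append(GuildAssignment.unassigned(otu))
        else:
            assignments.append(GuildAssignment(
                otu_id=otu, matched_taxon=hit.taxon, matched_rank=hit.level,
                guild=hit.guild, trophic_mode=hit.trophic_mode,
                confidence=hit.confidence, assigned=True,
            ))
    return assignments


def guild_composition(
    table: OTUTable, assignments: list[GuildAssignment], top_k: int | None = None
) -> pd.DataFrame:
    """Guild × sample relative-abundance matrix; columns sum to 1.

    With ``top_k``, rows beyond the k most abundant guilds (by overall
    mean) collapse into "Other"; "Undefined" is always kept as its own row.
    """
    by_otu = {a.otu_id: a.guild for a in assignments}
    missing = set(table.otu_ids) - set(by_otu)
    if missing:
        raise ValueError(f"assignments missing for OTUs: {sorted(missing)[:5]}")
    ra = relative_abundance(table)
    guilds = pd.Index([by_otu[o] for o in table.otu_ids], name="guild")
    comp = ra.groupby(guilds).sum()
    if top_k is not None and len(comp) > top_k:
        order = comp.mean(axis=1).sort_values(ascending=False)
        keep = [g for g in order.index if g != UNDEFINED][:top_k]
        keep = set(keep) | ({UNDEFINED} if UNDEFINED in comp.index else set())
        other = comp.loc[[g for g in comp.index if g not in keep]].sum(axis=0)
        comp = comp.loc[sorted(keep)]
        comp.loc["Other"] = other
    return comp


def trophic_mode_summary(
    table: OTUTable,
    assignments: list[GuildAssignment],
    metadata=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample and per-(group, timepoint) trophic-mode shares.

    An OTU's relative abundance is split equally across the modes named in
    its (possibly composite) trophic mode; unassigned OTUs count as
    Undefined.  Shares sum to 1 per sample.
    """
    meta = metadata if metadata is not None else table.metadata_frame()
    ra = relative_abundance(table)
    modes = list(TROPHIC_MODES) + [UNDEFINED]
    per_sample = pd.DataFrame(0.0, index=modes, columns=ra.columns)
    by_otu = {a.otu_id: a for a in assignments}
    for otu in table.otu_ids:
        a = by_otu[otu]
        parts = a.trophic_mode.split("-") if a.assigned else [UNDEFINED]
        share = ra.loc[otu] / len(parts)
        for m in parts:
            per_sample.loc[m] += share
    cell = per_sample.T.join(meta[["group", "timepoint"]])
    per_cell = cell.groupby(["group", "timepoint"], sort=True)[modes].mean()
    return per_sample, per_cell
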