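"""End-to-end orchestration: config, report bundle, and the CLI.

``run_all`` drives the full analysis — table preparation → diversity →
differential composition → guilds → per-stratum co-occurrence networks →
robustness — writing every result as TSV/JSON into an output directory
together with a run log recording stages, seeds and timings.  Re-running
the same config reproduces byte-identical numeric outputs: every
stochastic stage draws from its own explicit seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import click
import numpy as np
import yaml

from . import __version__
from . import compare, diversity, guilds, network, robustness, synth, tables

log = logging.getLogger("fungalnet")


@dataclass
class PipelineConfig:
    # inputs: either file paths or a synthetic template
    otu_table: str | None = None
    metadata: str | None = None
    guild_db: str | None = None
    template: str | None = None        # YAML template path; None → defaults
    samples_per_cell: int = 3
    # normalisation
    rarefaction: str = "min-sample"    # or "fixed"
    rarefaction_depth: int | None = None
    # thresholds
    top_k: int = 400
    min_mean_ra: float = 0.0002
    rho_threshold: float = 0.6
    p_threshold: float = 0.05
    fold_change: float = 4.0
    alpha: float = 0.05
    # permutation / null settings
    n_perm: int = 999
    null_reps: int = 100
    attack_reps: int = 10
    attack_step: float = 0.05
    bootstrap_reps: int = 1000
    network_stratification: str = "group"  # "group" | "timepoint" | "both"
    # seeds per stage
    seeds: dict = field(default_factory=lambda: {
        "simulate": 101, "rarefy": 102, "permutation": 103,
        "network": 104, "robustness": 105,
    })
    outdir: str = "results/run"

    def validate(self) -> None:
        if not (0.0 < self.rho_threshold < 1.0):
            raise ValueError("rho_threshold must lie in (0, 1)")
        if not (0.0 < self.p_threshold <= 1.0):
            raise ValueError("p_threshold must lie in (0, 1]")
        if self.fold_change <= 1.0:
            raise ValueError("fold_change must exceed 1")
        if self.rarefaction not in {"min-sample", "fixed"}:
            raise ValueError("rarefaction must be 'min-sample' or 'fixed'")
        if self.rarefaction == "fixed" and not self.rarefaction_depth:
            raise ValueError("fixed rarefaction needs rarefaction_depth")
        if self.network_stratification not in {"group", "timepoint", "both"}:
            raise ValueError("network_stratification must be group|timepoint|both")
        if self.top_k < 2 or self.n_perm < 99:
            raise ValueError("top_k ≥ 2 and n_perm ≥ 99 required")
        for stage in ("simulate", "rarefy", "permutation", "network", "robustness"):
            if stage not in self.seeds:
                raise ValueError(f"missing seed for stage {stage!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = cls(**doc)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _load_or_simulate(config: PipelineConfig, outdir: Path):
    if config.otu_table:
        table = tables.read_otu_table(config.otu_table)
        if config.metadata:
            table = tables.OTUTable(table.counts, table.taxonomy,
                                    tables.read_metadata(config.metadata))
        planted = None
    else:
        template = (synth.CommunityTemplate.from_yaml(config.template)
                    if config.template else synth.default_template())
        table, planted = synth.simulate_counts(
            template, samples_per_cell=config.samples_per_cell,
            seed=config.seeds["simulate"],
        )
        tables.write_otu_table(table, outdir / "otu_table.tsv")
        tables.write_metadata(table.metadata, outdir / "metadata.tsv")
        planted.to_frame().to_csv(outdir / "planted_edges.tsv", sep="\t",
                                  index=False)
    return table, planted


def run_all(config: PipelineConfig) -> Path:
    """Execute every stage; returns the report bundle directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = time.time()
    log.info("fungalnet %s run; seeds=%s", __version__, config.seeds)
    try:
        # -- tables --------------------------------------------------------
        stage = "tables"
        table, _ = _load_or_simulate(config, outdir)
        depth = (config.rarefaction_depth if config.rarefaction == "fixed"
                 else int(table.depths().min()))
        rarefied = tables.rarefy(table, depth, seed=config.seeds["rarefy"])
        log.info("stage=tables rarefied to depth %d", depth)
        tables.goods_coverage(rarefied).to_csv(outdir / "goods_coverage.tsv",
                                               sep="\t")
        shared = tables.shared_unique_counts(rarefied)
        _json_dump({"+".join(sorted(k)): v for k, v in shared.items()},
                   outdir / "shared_unique_otus.json")
        tables.ternary_coordinates(rarefied).to_csv(
            outdir / "ternary_coordinates.tsv", sep="\t")

        # -- diversity -----------------------------------------------------
        stage = "diversity"
        diversity.alpha_diversity_frame(rarefied).to_csv(
            outdir / "alpha_diversity.tsv", sep="\t")
        dm = diversity.bray_curtis(rarefied)
        dm.to_frame().to_csv(outdir / "bray_curtis.tsv", sep="\t")
        coords, explained = diversity.pcoa(dm)
        coords.iloc[:, :3].to_csv(outdir / "pcoa_coordinates.tsv", sep="\t")
        groups = [m.group for m in rarefied.metadata]
        seed_perm = config.seeds["permutation"]
        f_stat, f_p = diversity.permanova(dm, groups, n_perm=config.n_perm,
                                          seed=seed_perm)
        r_stat, r_p = diversity.anosim(dm, groups, n_perm=config.n_perm,
                                       seed=seed_perm)
        _json_dump({
            "permanova": {"statistic": f_stat, "p": f_p,
                          "n_perm": config.n_perm, "seed": seed_perm},
            "anosim": {"statistic": r_stat, "p": r_p,
                       "n_perm": config.n_perm, "seed": seed_perm},
            "pcoa_explained": [float(e) for e in explained[:3]],
        }, outdir / "beta_diversity_tests.json")
        diversity.pairwise_anosim(dm, groups, n_perm=config.n_perm,
                                  seed=seed_perm).to_csv(
            outdir / "pairwise_anosim.tsv", sep="\t", index=False)
        log.info("stage=diversity permanova F=%.3f p=%.4f", f_stat, f_p)

        # -- differential composition --------------------------------------
        stage = "compare"
        phylum_table = tables.aggregate_by_rank(rarefied, "phylum")
        kw = compare.group_test_by_taxon(phylum_table, mode="three-group-KW",
                                         alpha=config.alpha)
        compare.differential_frame(kw).to_csv(
            outdir / "differential_phylum_kw.tsv", sep="\t", index=False)
        group_names = sorted(set(groups))
        for a, b in zip(group_names, group_names[1:] + group_names[:1]):
            res = compare.volcano_differential(
                rarefied, a, b, fc_thresh=config.fold_change,
                p_thresh=config.p_threshold)
            compare.differential_frame(res).to_csv(
                outdir / f"volcano_{b}-{a}.tsv", sep="\t", index=False)
        log.info("stage=compare done")

        # -- guilds --------------------------------------------------------
        stage = "guilds"
        db = guilds.load_guild_db(config.guild_db)
        assignments = guilds.assign_guilds(rarefied, db)
        guilds.guild_composition(rarefied, assignments, top_k=10).to_csv(
            outdir / "guild_composition.tsv", sep="\t")
        per_sample, per_cell = guilds.trophic_mode_summary(rarefied, assignments)
        per_sample.to_csv(outdir / "trophic_modes_per_sample.tsv", sep="\t")
        per_cell.to_csv(outdir / "trophic_modes_per_cell.tsv", sep="\t")
        log.info("stage=guilds %d/%d OTUs assigned",
                 sum(a.assigned for a in assignments), len(assignments))

        # -- networks ------------------------------------------------------
        stage = "network"
        meta = rarefied.metadata_frame()
        strata: dict[str, list[str]] = {}
        if config.network_stratification in {"group", "both"}:
            for g in sorted(meta["group"].unique()):
                strata[g] = list(meta.index[meta["group"] == g])
        if config.network_stratification in {"timepoint", "both"}:
            for t in sorted(meta["timepoint"].unique()):
                strata[t] = list(meta.index[meta["timepoint"] == t])
        partitions = {}
        nets = {}
        for name, samples in strata.items():
            sub = rarefied.subset_samples(samples)
            net = network.network_from_table(
                sub, k=config.top_k, min_mean_ra=config.min_mean_ra,
                rho_threshold=config.rho_threshold,
                p_threshold=config.p_threshold)
            nets[name] = net
            if net.n_nodes == 0:
                log.info("stage=network stratum=%s empty network", name)
                continue
            topo = network.topology(net, null_reps=config.null_reps,
                                    seed=config.seeds["network"])
            partitions[name] = topo.module_partition
            net.edge_frame().to_csv(outdir / f"network_{name}_edges.tsv",
                                    sep="\t", index=False)
            net.node_frame(topo.module_partition).to_csv(
                outdir / f"network_{name}_nodes.tsv", sep="\t", index=False)
            _json_dump(topo.as_dict(), outdir / f"topology_{name}.json")
            log.info("stage=network stratum=%s nodes=%d edges=%d", name,
                     topo.n_nodes, topo.n_edges)
        names = sorted(partitions)
        sim_rows = []
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                cnt, _ = network.module_similarity(partitions[a], partitions[b])
                sim_rows.append({"stratum_a": a, "stratum_b": b,
                                 "similar_modules": cnt})
        _json_dump(sim_rows, outdir / "module_similarity.json")

        # -- robustness ----------------------------------------------------
        stage = "robustness"
        for name, net in nets.items():
            if net.n_nodes == 0:
                continue
            for strat in ("random", "degree-targeted"):
                curve = robustness.attack_curve(
                    net, strategy=strat, step=config.attack_step,
                    reps=config.attack_reps, seed=config.seeds["robustness"])
                curve.to_frame().to_csv(
                    outdir / f"attack_{name}_{strat}.tsv", sep="\t",
                    index=False)
        stab = robustness.stability_contrast(
            rarefied, reps=config.bootstrap_reps,
            seed=config.seeds["robustness"])
        robustness.stability_frame(stab).to_csv(
            outdir / "stability_contrast.tsv", sep="\t", index=False)
        log.info("run complete in %.1f s", time.time() - t0)
    except Exception as exc:
        log.error("stage=%s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    return outdir


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
@click.version_option(__version__)
def cli():
    """Soil fungal community analysis pipeline."""


@cli.command()
@click.option("--template", type=click.Path(exists=True), default=None,
              help="Community template YAML (default: built-in).")
@click.option("--samples-per-cell", default=3, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", type=click.Path(), required=True,
              help="Output directory for table/metadata/ground-truth TSVs.")
def simulate(template, samples_per_cell, seed, out):
    """Generate a synthetic OTU table with planted correlation blocks."""
    tmpl = (synth.CommunityTemplate.from_yaml(template) if template
            else synth.default_template())
    table, planted = synth.simulate_counts(tmpl, samples_per_cell, seed)
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    tables.write_otu_table(table, outdir / "otu_table.tsv")
    tables.write_metadata(table.metadata, outdir / "metadata.tsv")
    planted.to_frame().to_csv(outdir / "planted_edges.tsv", sep="\t", index=False)
    click.echo(f"wrote {table.shape[0]} OTUs x {table.shape[1]} samples to {out}")


def _read_table(otu_table, metadata):
    table = tables.read_otu_table(otu_table)
    if metadata:
        table = tables.OTUTable(table.counts, table.taxonomy,
                                tables.read_metadata(metadata))
    return table


@cli.command("diversity")
@click.option("--otu-table", type=click.Path(exists=True), required=True)
@click.option("--metadata", type=click.Path(exists=True), default=None)
@click.option("--n-perm", default=999, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def diversity_cmd(otu_table, metadata, n_perm, seed, out):
    """Alpha diversity, Bray-Curtis, PCoA and permutation tests."""
    table = _read_table(otu_table, metadata)
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    diversity.alpha_diversity_frame(table).to_csv(
        outdir / "alpha_diversity.tsv", sep="\t")
    dm = diversity.bray_curtis(table)
    dm.to_frame().to_csv(outdir / "bray_curtis.tsv", sep="\t")
    groups = [m.group for m in table.metadata]
    if len(set(groups)) >= 2:
        f, fp = diversity.permanova(dm, groups, n_perm=n_perm, seed=seed)
        r, rp = diversity.anosim(dm, groups, n_perm=n_perm, seed=seed)
        _json_dump({"permanova": {"statistic": f, "p": fp, "n_perm": n_perm,
                                  "seed": seed},
                    "anosim": {"statistic": r, "p": rp, "n_perm": n_perm,
                               "seed": seed}},
                   outdir / "beta_diversity_tests.json")
    click.echo(f"diversity results written to {out}")


@cli.command()
@click.option("--otu-table", type=click.Path(exists=True), required=True)
@click.option("--metadata", type=click.Path(exists=True), default=None)
@click.option("--group-a", required=True)
@click.option("--group-b", required=True)
@click.option("--fc", default=4.0, show_default=True)
@click.option("--p", "p_thresh", default=0.05, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def differential(otu_table, metadata, group_a, group_b, fc, p_thresh, out):
    """Volcano-style differential OTUs between two groups."""
    table = _read_table(otu_table, metadata)
    res = compare.volcano_differential(table, group_a, group_b,
                                       fc_thresh=fc, p_thresh=p_thresh)
    Path(out).parent.mkdir(parents=True, exist_ok=True)
    compare.differential_frame(res).to_csv(out, sep="\t", index=False)
    n_sig = sum(r.status != "ns" for r in res)
    click.echo(f"{n_sig} differential OTUs written to {out}")


@cli.command("guilds")
@click.option("--otu-table", type=click.Path(exists=True), required=True)
@click.option("--metadata", type=click.Path(exists=True), default=None)
@click.option("--guild-db", type=click.Path(exists=True), default=None)
@click.option("--out", type=click.Path(), required=True)
def guilds_cmd(otu_table, metadata, guild_db, out):
    """Guild assignment and trophic-mode summaries."""
    table = _read_table(otu_table, metadata)
    db = guilds.load_guild_db(guild_db)
    assignments = guilds.assign_guilds(table, db)
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    guilds.guild_composition(table, assignments).to_csv(
        outdir / "guild_composition.tsv", sep="\t")
    per_sample, per_cell = guilds.trophic_mode_summary(table, assignments)
    per_sample.to_csv(outdir / "trophic_modes_per_sample.tsv", sep="\t")
    per_cell.to_csv(outdir / "trophic_modes_per_cell.tsv", sep="\t")
    click.echo(f"guild results written to {out}")


@cli.command("network")
@click.option("--otu-table", type=click.Path(exists=True), required=True)
@click.option("--metadata", type=click.Path(exists=True), default=None)
@click.option("--rho", default=0.6, show_default=True)
@click.option("--p", "p_thresh", default=0.05, show_default=True)
@click.option("--top-k", default=400, show_default=True)
@click.option("--null-reps", default=100, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def network_cmd(otu_table, metadata, rho, p_thresh, top_k, null_reps, seed, out):
    """Build a co-occurrence network and its topology panel."""
    table = _read_table(otu_table, metadata)
    net = network.network_from_table(table, k=top_k, rho_threshold=rho,
                                     p_threshold=p_thresh)
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    net.edge_frame().to_csv(outdir / "edges.tsv", sep="\t", index=False)
    if net.n_nodes:
        topo = network.topology(net, null_reps=null_reps, seed=seed)
        net.node_frame(topo.module_partition).to_csv(
            outdir / "nodes.tsv", sep="\t", index=False)
        _json_dump(topo.as_dict(), outdir / "topology.json")
        click.echo(f"network: {topo.n_nodes} nodes, {topo.n_edges} edges")
    else:
        click.echo("network is empty under the thresholds")


@cli.command("robustness")
@click.option("--otu-table", type=click.Path(exists=True), required=True)
@click.option("--metadata", type=click.Path(exists=True), default=None)
@click.option("--strategy", type=click.Choice(["random", "degree-targeted"]),
              default="random", show_default=True)
@click.option("--reps", default=100, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def robustness_cmd(otu_table, metadata, strategy, reps, seed, out):
    """Attack curve of the table's co-occurrence network."""
    table = _read_table(otu_table, metadata)
    net = network.network_from_table(table)
    curve = robustness.attack_curve(net, strategy=strategy, reps=reps, seed=seed)
    Path(out).parent.mkdir(parents=True, exist_ok=True)
    curve.to_frame().to_csv(out, sep="\t", index=False)
    click.echo(f"attack curve written to {out}")


@cli.command("run-all")
@click.option("--config", "config_path", type=click.Path(exists=True),
              default=None, help="Pipeline config YAML (default: synthetic run).")
@click.option("--out", type=click.Path(), default=None,
              help="Override the config's output directory.")
@click.option("--seed", type=int, default=None,
              help="Override every stage seed (offsets applied per stage).")
def run_all_cmd(config_path, out, seed):
    """Run every stage end-to-end and write the report bundle."""
    config = (PipelineConfig.from_yaml(config_path) if config_path
              else PipelineConfig())
    if out:
        config.outdir = out
    if seed is not None:
        config.seeds = {k: int(seed) + i for i, k in
                        enumerate(["simulate", "rarefy", "permutation",
                                   "network", "robustness"])}
    outdir = run_all(config)
    click.echo(f"report bundle written to {outdir}")
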