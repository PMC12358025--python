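"""Configuration-driven orchestration of the full diversity analysis.

Stages run in dependency order on either user-supplied files or a
simulated dataset: genetic statistics (GS/GD, diversity), UPGMA tree,
PCoA, admixture clustering with deltaK model choice, cytoplasm typing,
and the seed/trait analyses.  All randomness derives from one master
seed, so a rerun with the same configuration reproduces the bundle
exactly, stochastic stages included.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import admixture as adm
from . import clustering as clu
from . import cytoplasm as cyt
from . import genetic_stats as gstats
from . import traits as trt
from .data_model import (
    DataError,
    load_dataset,
    load_trait_table,
    write_distance_phylip,
)
from .simulate import SimSpec, simulate_dataset

logger = logging.getLogger("melodiv.pipeline")

__all__ = ["PipelineConfig", "PipelineError", "ReportBundle", "run_pipeline"]

ALL_STAGES = ("stats", "tree", "pcoa", "admixture", "cytoplasm", "traits")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs plus analysis settings.

    Either ``simulate`` or the file paths must be provided.  Admixture
    defaults re-enact the standard survey protocol (K = 1-10, 20 runs,
    5000/5000 burn-in/collection, membership threshold 0.6); scale them
    down for exploratory runs.
    """

    simulate: SimSpec | None = None
    genotype_path: str | None = None
    metadata_path: str | None = None
    panel_path: str | None = None
    traits_path: str | None = None
    caps_path: str | None = None
    cytoplasm_key_path: str | None = None
    stages: tuple[str, ...] = ALL_STAGES
    k_min: int = 1
    k_max: int = 10
    n_runs: int = 20
    burn_in: int = 5000
    iterations: int = 5000
    frequency_model: str = "correlated"
    assignment_threshold: float = 0.6
    morph_clusters: int = 4
    pcoa_axes: int = 2
    outdir: str | None = None
    master_seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise DataError(f"unknown stages: {sorted(unknown)}")
        if not 1 <= self.k_min <= self.k_max:
            raise DataError("invalid K range")
        if self.simulate is None and self.genotype_path is None:
            raise DataError("provide either a simulation spec or input paths")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All tables produced by one pipeline run."""

    config_hash: str
    master_seed: int
    gs: pd.DataFrame | None = None
    gd: "gstats.DistanceMatrix | None" = None
    diversity: pd.DataFrame | None = None
    newick: str | None = None
    pcoa: clu.OrdinationResult | None = None
    delta_k: pd.DataFrame | None = None
    consensus_q: pd.DataFrame | None = None
    assignments: pd.Series | None = None
    best_k: int | None = None
    cytoplasm_types: cyt.CytoplasmTypeTable | None = None
    cytoplasm_crosstab: pd.DataFrame | None = None
    seed_class_table: gstats.ContingencyTable | None = None
    seed_chi2: gstats.ChiSquareResult | None = None
    morph_labels: pd.Series | None = None
    morph_newick: str | None = None
    trait_pca: clu.OrdinationResult | None = None
    log: list[dict] = field(default_factory=list)


def _load_inputs(cfg: PipelineConfig):
    if cfg.simulate is not None:
        sim = simulate_dataset(cfg.simulate)
        return sim.genotypes, sim.metadata, sim.traits, sim.caps_calls, sim.cytoplasm_key
    g, meta = load_dataset(cfg.genotype_path, cfg.metadata_path, cfg.panel_path)
    traits_tbl = load_trait_table(cfg.traits_path) if cfg.traits_path else None
    calls = (
        pd.read_csv(cfg.caps_path, sep="\t", index_col=0, dtype=str)
        if cfg.caps_path
        else None
    )
    key = (
        cyt.CytoplasmKey.from_yaml(cfg.cytoplasm_key_path)
        if cfg.cytoplasm_key_path
        else None
    )
    return g, meta, traits_tbl, calls, key


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Execute the requested stages; a stage failure aborts with its name."""
    bundle = ReportBundle(config_hash=cfg.config_hash(), master_seed=cfg.master_seed)
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def stage(name: str, fn) -> None:
        if name not in cfg.stages:
            logger.info("stage %s skipped", name)
            return
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            bundle.log.append({"stage": name, "status": "failed", "error": str(exc)})
            _write_log(bundle, outdir)
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        dt = time.perf_counter() - t0
        bundle.log.append({"stage": name, "status": "ok", "seconds": round(dt, 3)})
        logger.info("stage %s done in %.2fs", name, dt)

    g, meta, traits_tbl, calls, key = _load_inputs(cfg)
    grouping = {r.id: r.region_group for r in (meta or [])}

    def do_stats() -> None:
        bundle.gs = gstats.gs_matrix(g)
        bundle.gd = gstats.gd_matrix(g)
        freqs = gstats.allele_freqs(g, grouping or None)
        dom = [mk.name for mk in g.markers if mk.is_dominant]
        codom = [mk.name for mk in g.markers if not mk.is_dominant]
        rows = []
        for grp in freqs.groups:
            row = {
                "group": grp,
                "n": freqs.sample_sizes[grp],
                "D_combined": gstats.gene_diversity(freqs, grp),
            }
            if dom:
                row["D_dominant"] = gstats.gene_diversity(freqs, grp, markers=dom)
            if codom:
                row["D_codominant"] = gstats.gene_diversity(freqs, grp, markers=codom)
            rows.append(row)
        bundle.diversity = pd.DataFrame(rows).set_index("group")
        if outdir:
            bundle.gs.to_csv(outdir / "gs_matrix.tsv", sep="\t")
            write_distance_phylip(bundle.gd, outdir / "gd_matrix.phy")
            bundle.diversity.to_csv(outdir / "diversity.tsv", sep="\t")

    def do_tree() -> None:
        if bundle.gd is None:
            bundle.gd = gstats.gd_matrix(g)
        tree = clu.upgma(bundle.gd)
        bundle.newick = clu.to_newick(tree)
        if outdir:
            (outdir / "upgma.nwk").write_text(bundle.newick + "\n")

    def do_pcoa() -> None:
        if bundle.gd is None:
            bundle.gd = gstats.gd_matrix(g)
        bundle.pcoa = clu.pcoa(bundle.gd, n_axes=cfg.pcoa_axes)
        if outdir:
            bundle.pcoa.coordinates.to_csv(outdir / "pcoa_coordinates.tsv", sep="\t")

    def do_admixture() -> None:
        base = adm.AdmixtureConfig(
            K=1,
            burn_in=cfg.burn_in,
            iterations=cfg.iterations,
            n_runs=cfg.n_runs,
            frequency_model=cfg.frequency_model,
        )
        ks = list(range(cfg.k_min, cfg.k_max + 1))
        runs = adm.run_structure(g, ks, base, master_seed=cfg.master_seed)
        if len(ks) >= 3 and cfg.n_runs >= 2:
            bundle.delta_k = adm.delta_k(runs)
            defined = bundle.delta_k["delta_K"].dropna()
            bundle.best_k = int(defined.idxmax()) if len(defined) else ks[0]
        else:
            bundle.best_k = ks[-1]
        _, consensus = adm.align_runs(runs[bundle.best_k], bundle.best_k)
        bundle.consensus_q = consensus
        bundle.assignments = adm.assign_populations(
            consensus, threshold=cfg.assignment_threshold
        )
        if outdir:
            if bundle.delta_k is not None:
                bundle.delta_k.to_csv(outdir / "delta_k.tsv", sep="\t")
            consensus.to_csv(outdir / "consensus_q.tsv", sep="\t")
            bundle.assignments.to_csv(outdir / "assignments.tsv", sep="\t")
            run_log = [
                {"K": k, "run": i, "seed": r.seed, "lnPD": r.lnPD}
                for k, rs in runs.items()
                for i, r in enumerate(rs)
            ]
            with open(outdir / "admixture_runs.jsonl", "w") as fh:
                for rec in run_log:
                    fh.write(json.dumps(rec) + "\n")

    def do_cytoplasm() -> None:
        if calls is None or key is None:
            raise DataError("cytoplasm stage needs CAPS calls and a key")
        bundle.cytoplasm_types = cyt.classify_cytoplasm(calls, key)
        table, _excluded = cyt.type_by_group_crosstab(bundle.cytoplasm_types, meta)
        bundle.cytoplasm_crosstab = table
        if outdir:
            bundle.cytoplasm_types.types.to_csv(outdir / "cytoplasm_types.tsv", sep="\t")
            table.to_csv(outdir / "cytoplasm_crosstab.tsv", sep="\t")

    def do_traits() -> None:
        bundle.seed_class_table = trt.seed_class_table(meta)
        t = bundle.seed_class_table
        if len(t.row_labels) >= 2:
            bundle.seed_chi2 = gstats.chi_square_independence(t)
        if traits_tbl is not None:
            labels, tree = trt.morph_cluster(
                traits_tbl, min(cfg.morph_clusters, traits_tbl.shape[0])
            )
            bundle.morph_labels = labels
            bundle.morph_newick = clu.to_newick(tree)
            bundle.trait_pca = clu.pca(clu.standardize(traits_tbl), n_axes=2)
        if outdir:
            t.to_frame().to_csv(outdir / "seed_class_table.tsv", sep="\t")
            if bundle.morph_labels is not None:
                bundle.morph_labels.to_csv(outdir / "morph_clusters.tsv", sep="\t")

    stage("stats", do_stats)
    stage("tree", do_tree)
    stage("pcoa", do_pcoa)
    stage("admixture", do_admixture)
    stage("cytoplasm", do_cytoplasm)
    stage("traits", do_traits)
    _write_log(bundle, outdir)
    return bundle


def _write_log(bundle: ReportBundle, outdir: Path | None) -> None:
    if outdir is None:
        return
    with open(outdir / "run_log.jsonl", "w") as fh:
        header = {
            "config_hash": bundle.config_hash,
            "master_seed": bundle.master_seed,
        }
        fh.write(json.dumps(header) + "\n")
        for rec in bundle.log:
            fh.write(json.dumps(rec) + "\n")
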