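"""End-to-end orchestration: simulate/map/DE/bootstrap/enrich/celltypes/report.

A single config (YAML or :class:`RunConfig`) drives the whole analysis; all
randomness flows from one seed through stage-specific substreams, so a rerun
with the same config and seed reproduces every output file byte-for-byte.
Outputs are plain TSV tables plus a machine-readable ``summary.json`` and a
``run.log``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import atlas_io, celltypes, enrichment, mask_mapping, meta_de, synthetic

logger = logging.getLogger("stressmap")

SPECIAL_SETS = (
    "receptor_universe",
    "neuropeptides",
    "gr_targets_only",
    "mr_targets_only",
    "gr_mr_targets",
)


@dataclass
class RunConfig:
    """One config for the full pipeline.

    In simulation mode (default) the synthetic generators provide every
    input; otherwise ``manifest``, ``mask`` and optionally ``gene_sets`` and
    single-cell paths point at files on disk.
    """

    outdir: str = "stressmap_run"
    seed: int = 0
    simulate: bool = True
    sim: dict = field(default_factory=dict)
    manifest: str | None = None
    mask: str | None = None
    gene_sets: str | None = None
    sc_counts: str | None = None
    sc_genes: str | None = None
    sc_cells: str | None = None
    scopes: list[str] = field(default_factory=lambda: ["cortex"])
    alpha: float = 0.05
    go_alpha: float = 0.001
    background_fraction: float = 0.2
    bootstrap_B: int = 100
    bootstrap_n: int = 111
    min_in_samples: int = 2
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.go_alpha < 1:
            raise ValueError("alpha levels must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


def _setup_run_logger(outdir: Path, level: str) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    # no timestamps: reruns must be byte-identical
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(level)
    return handler


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-tagged per stage
                raise StageError(f"[{name}] {exc}") from exc

        return inner

    return wrap


def summarize_direction(de: pd.DataFrame) -> tuple[int, int, int]:
    """Counts of (higher, lower, total) significant genes; see meta_de."""
    return meta_de.summarize_direction(de)


@_stage("inputs")
def _load_inputs(cfg: RunConfig):
    if cfg.simulate:
        sim = synthetic.SimConfig(**{**cfg.sim, "seed": cfg.seed})
        donors, samples, truth = synthetic.generate_atlas(sim)
        mask = synthetic.generate_mask(sim)
        collection = synthetic.generate_gene_sets(truth, sim)
        sc_counts, sc_genes, sc_cells = synthetic.generate_sc(
            sim, planted_genes=truth.planted_genes
        )
        return donors, samples, mask, collection, (sc_counts, sc_genes, sc_cells)
    if not cfg.manifest or not cfg.mask:
        raise ValueError("non-simulated runs need manifest and mask paths")
    donors, frames = [], []
    for matrix_path, annotation_path in atlas_io.read_manifest(cfg.manifest):
        expr, ann = atlas_io.read_expression(matrix_path, annotation_path)
        donors.append(expr)
        frames.append(ann)
    samples = pd.concat(frames, ignore_index=True)
    mask = atlas_io.read_mask(cfg.mask)
    collection = atlas_io.read_gene_sets(cfg.gene_sets) if cfg.gene_sets else None
    sc = None
    if cfg.sc_counts:
        sc = atlas_io.read_sc_counts(cfg.sc_counts, cfg.sc_genes, cfg.sc_cells)
        sc = (sc[0], sc[1], sc[2])
    return donors, samples, mask, collection, sc


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute map -> DE -> bootstrap -> enrichment -> celltypes -> report.

    Returns the output directory.  Any stage failure raises
    :class:`StageError` with a stage-tagged message; output files written
    before the failure are retained.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logger(outdir, cfg.log_level)
    summary: dict = {"seed": cfg.seed, "config": dataclasses.asdict(cfg)}
    try:
        logger.info("config: %s", json.dumps(dataclasses.asdict(cfg), sort_keys=True))
        donors, samples, mask, collection, sc = _load_inputs(cfg)
        gene_ids = donors[0].gene_ids

        membership = _map_stage(samples, mask, outdir)
        de_tables = _de_stage(cfg, donors, membership, outdir, summary)
        de_cortex = de_tables.get("cortex")
        de_genes = (
            de_cortex.loc[de_cortex["significant"], "gene_id"].tolist()
            if de_cortex is not None
            else []
        )
        _bootstrap_stage(cfg, donors, membership, de_genes, outdir, summary)
        if collection is not None:
            _enrich_stage(cfg, donors, membership, collection, de_genes, gene_ids, outdir, summary)
        if sc is not None and de_genes:
            _celltypes_stage(sc, de_genes, outdir, summary)
        with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return outdir
    finally:
        logger.removeHandler(handler)
        handler.close()


@_stage("map")
def _map_stage(samples, mask, outdir) -> pd.DataFrame:
    membership = mask_mapping.assign_membership(samples, mask)
    atlas_io.write_table(membership, outdir / "membership.tsv")
    n_in = int(membership["in_network"].sum())
    logger.info("membership: %d in-network / %d out", n_in, len(membership) - n_in)
    return membership


@_stage("de")
def _de_stage(cfg, donors, membership, outdir, summary) -> dict[str, pd.DataFrame]:
    tables = {}
    summary["de"] = {}
    for scope in cfg.scopes:
        spec = mask_mapping.ContrastSpec(scope=scope, min_in_samples=cfg.min_in_samples)
        de = meta_de.run_de(donors, membership, spec, alpha=cfg.alpha)
        fname = f"de_{scope.replace(':', '_')}.tsv"
        atlas_io.write_table(de, outdir / fname)
        n_up, n_down, n_sig = meta_de.summarize_direction(de)
        summary["de"][scope] = {"n_up": n_up, "n_down": n_down, "n_significant": n_sig}
        logger.info("DE %s: %d significant (%d up / %d down)", scope, n_sig, n_up, n_down)
        tables[scope] = de
    return tables


@_stage("bootstrap")
def _bootstrap_stage(cfg, donors, membership, de_genes, outdir, summary) -> None:
    if cfg.bootstrap_B <= 0:
        return
    n_cortex = int(membership["is_cortex"].sum())
    n = min(cfg.bootstrap_n, n_cortex)
    report = meta_de.bootstrap_stability(
        donors,
        membership,
        reference_de=de_genes,
        B=cfg.bootstrap_B,
        n_resample=n,
        seed=cfg.seed + 1,
        alpha=cfg.alpha,
    )
    atlas_io.write_table(report.to_frame(), outdir / "stability_frequency.tsv")
    summary["bootstrap"] = {
        "B": report.B,
        "n_resample": report.n_resample,
        "fraction_iterations_with_overlap": report.fraction_iterations_with_overlap,
        "mean_overlap": float(pd.Series(report.per_iteration_overlap).mean())
        if report.per_iteration_overlap
        else 0.0,
    }


@_stage("enrich")
def _enrich_stage(cfg, donors, membership, collection, de_genes, gene_ids, outdir, summary) -> None:
    marker_sets = atlas_io.GeneSetCollection(
        name=collection.name,
        sets={k: v for k, v in collection.sets.items() if k not in SPECIAL_SETS},
    )
    res = enrichment.enrich_collection(de_genes, marker_sets, gene_ids, alpha=cfg.alpha)
    atlas_io.write_table(res, outdir / "enrichment_sets.tsv")
    background = enrichment.expression_background(
        donors, membership, fraction=cfg.background_fraction
    )
    res_bg = enrichment.enrich_collection(
        [g for g in de_genes if g in set(background)],
        marker_sets,
        background,
        alpha=cfg.go_alpha,
    )
    atlas_io.write_table(res_bg, outdir / "enrichment_sets_expression_background.tsv")
    summary["enrichment"] = {
        "n_tests": int(len(res)),
        "n_enriched": int((res["direction"] == "enriched").sum()) if len(res) else 0,
        "top_set": res.iloc[0]["set_name"] if len(res) else None,
    }
    if "receptor_universe" in collection.sets:
        rec = enrichment.receptor_or(
            de_genes,
            marker_sets,
            collection.sets["receptor_universe"],
            collection.sets.get("neuropeptides"),
        )
        atlas_io.write_table(rec, outdir / "receptor_or.tsv", sort_by=["trait"])
    if "gr_targets_only" in collection.sets:
        grmr = enrichment.grmr_enrichment(
            de_genes,
            collection.sets["gr_targets_only"],
            collection.sets["mr_targets_only"],
            collection.sets["gr_mr_targets"],
            gene_ids,
        )
        atlas_io.write_table(grmr, outdir / "grmr_enrichment.tsv")
        summary["grmr"] = {
            r["set_name"]: None if pd.isna(r["p_adj"]) else float(r["p_adj"])
            for _, r in grmr.iterrows()
        }


@_stage("celltypes")
def _celltypes_stage(sc, de_genes, outdir, summary) -> None:
    counts, sc_gene_ids, cells = sc
    profiles = celltypes.cluster_scores(
        counts,
        sc_gene_ids,
        cells["cluster_id"].tolist(),
        cells["cell_class"].tolist(),
        de_genes,
    )
    atlas_io.write_table(celltypes.profiles_to_frame(profiles), outdir / "cluster_scores.tsv")
    w, p = celltypes.class_comparison(profiles)
    summary["celltypes"] = {"wilcoxon_W": w, "wilcoxon_p": p, "n_clusters": len(profiles)}
    logger.info("celltypes: W=%g p=%g over %d clusters", w, p, len(profiles))
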