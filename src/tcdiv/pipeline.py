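"""End-to-end orchestration: simulate -> normalize -> QC -> score -> DE ->
cluster -> overlap -> enrich, with a YAML run manifest.

Every stage is a pure function of its declared inputs, so an identical
config + seed reproduces byte-identical output tables.  Thresholds
(percentile, FDR alpha, k, pseudocounts) come exclusively from the
:class:`~tcdiv.data_model.AnalysisConfig` — there are no hidden
constants.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .data_model import (
    AnalysisConfig,
    ConfigError,
    GeneSetCollection,
    write_gmt,
    write_matrix,
    write_ortholog_map,
    write_sample_sheet,
    write_table,
)
from .divergence import score_all
from .enrichment import fisher_enrichment
from .preprocess import normalize_to_baseline, replicate_correlation_qc, rna_protein_correlation
from .synthetic import ArchetypeSpec, DEFAULT_SPECS, simulate_timecourse, truth_auroc
from .timecourse_de import cluster_profiles, cross_layer_overlap, per_timepoint_de

__all__ = ["specs_from_config", "run_all"]

log = logging.getLogger("tcdiv")


def specs_from_config(raw: dict) -> list[ArchetypeSpec]:
    """Archetype mix from the ``synthetic.archetypes`` config section."""
    section = (raw or {}).get("synthetic", {}).get("archetypes")
    if not section:
        return list(DEFAULT_SPECS)
    try:
        return [ArchetypeSpec(**entry) for entry in section]
    except TypeError as exc:
        raise ConfigError(f"bad archetype entry: {exc}") from exc


def run_all(
    config: AnalysisConfig,
    outdir: str | Path,
    raw_config: dict | None = None,
) -> dict:
    """Run the full synthetic-data pipeline and write a YAML manifest.

    Returns the manifest dict (config echo, seed, per-stage output paths
    and row counts, version).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
    }

    def record(stage: str, name: str, path: Path, n_rows: int) -> None:
        manifest["stages"].setdefault(stage, {})[name] = {
            "path": str(path), "rows": int(n_rows),
        }

    # -- simulate ----------------------------------------------------------
    log.info("stage simulate: generating synthetic two-group time course")
    specs = specs_from_config(raw_config or {})
    sim = simulate_timecourse(specs, seed=config.seed)
    ga, gb = sim.sheet.groups
    write_sample_sheet(sim.sheet, outdir / "sample_sheet.tsv")
    record("simulate", "sample_sheet", outdir / "sample_sheet.tsv", len(sim.sheet.frame))
    for layer, mats in (("rna", sim.rna), ("protein", sim.protein)):
        for g, mat in mats.items():
            p = outdir / f"{layer}_{g}.tsv"
            write_matrix(mat, p)
            record("simulate", f"{layer}_{g}", p, len(mat.values))
    write_ortholog_map(sim.ortholog_map, outdir / "ortholog_map.tsv")
    record("simulate", "ortholog_map", outdir / "ortholog_map.tsv", len(sim.ortholog_map))
    truth = sim.truth.labels.rename_axis("feature_id").reset_index()
    write_table(truth, outdir / "truth_labels.tsv", index=False)
    record("simulate", "truth_labels", outdir / "truth_labels.tsv", len(truth))

    # -- normalize ---------------------------------------------------------
    log.info("stage normalize: baseline-anchored log2 ratios")
    profiles = {}
    for layer, mats, pc in (
        ("rna", sim.rna, config.pseudocount_rna),
        ("protein", sim.protein, 0.0),
    ):
        for g, mat in mats.items():
            prof = normalize_to_baseline(mat, pseudocount=pc, aggregate=config.aggregate)
            profiles[(layer, g)] = prof
            p = outdir / f"profiles_{layer}_{g}.tsv"
            out = prof.curves.copy()
            out.index.name = "feature_id"
            write_table(out, p)
            record("normalize", f"profiles_{layer}_{g}", p, len(out))
            xp = outdir / f"excluded_{layer}_{g}.tsv"
            write_table(prof.excluded, xp, index=False)
            record("normalize", f"excluded_{layer}_{g}", xp, len(prof.excluded))

    # -- qc ----------------------------------------------------------------
    log.info("stage qc: replicate and cross-layer correlations")
    qc_frames = []
    for layer, mats in (("rna", sim.rna), ("protein", sim.protein)):
        for g, mat in mats.items():
            rep = replicate_correlation_qc(mat, pseudocount=1.0)
            rep_pairs = rep.pairs.assign(layer=layer)
            qc_frames.append(rep_pairs)
    qc = pd.concat(qc_frames, ignore_index=True)
    write_table(qc, outdir / "qc_replicate_correlation.tsv", index=False)
    record("qc", "replicate_correlation", outdir / "qc_replicate_correlation.tsv", len(qc))
    xl = []
    for g in (ga, gb):
        cor = rna_protein_correlation(profiles[("rna", g)], profiles[("protein", g)])
        xl.append(cor.assign(group=g))
    xl = pd.concat(xl, ignore_index=True)
    write_table(xl, outdir / "qc_rna_protein_correlation.tsv", index=False)
    record("qc", "rna_protein_correlation", outdir / "qc_rna_protein_correlation.tsv", len(xl))

    # -- score -------------------------------------------------------------
    log.info("stage score: divergence score per ortholog pair")
    scores = {}
    for layer in ("protein", "rna"):
        table = score_all(
            profiles[(layer, ga)], profiles[(layer, gb)], sim.ortholog_map,
            q=config.percentile_q,
            include_baseline=config.include_baseline_in_shape,
            area_method=config.area_method,
        )
        scores[layer] = table
        p = outdir / f"scores_{layer}.tsv"
        write_table(table, p, index=False)
        record("score", f"scores_{layer}", p, len(table))

    # -- de ----------------------------------------------------------------
    log.info("stage de: per-timepoint Welch tests with BH FDR")
    de = {}
    for layer, mats, pc in (
        ("rna", sim.rna, config.pseudocount_rna),
        ("protein", sim.protein, 0.0),
    ):
        frames = [
            per_timepoint_de(mat, fdr_alpha=config.fdr_alpha, pseudocount=pc)
            for mat in mats.values()
        ]
        de[layer] = pd.concat(frames, ignore_index=True)
        p = outdir / f"de_{layer}.tsv"
        write_table(de[layer], p, index=False)
        record("de", f"de_{layer}", p, len(de[layer]))

    # -- cluster -----------------------------------------------------------
    log.info("stage cluster: Ward clustering of paired temporal profiles")
    assign = cluster_profiles(
        profiles[("protein", ga)], profiles[("protein", gb)],
        sim.ortholog_map, k=config.n_clusters,
    )
    lab = assign.labels.rename_axis("feature_id").reset_index()
    write_table(lab, outdir / "clusters_protein.tsv", index=False)
    record("cluster", "clusters_protein", outdir / "clusters_protein.tsv", len(lab))
    write_table(assign.mean_profiles, outdir / "cluster_mean_profiles.tsv")
    record("cluster", "mean_profiles", outdir / "cluster_mean_profiles.tsv",
           len(assign.mean_profiles))

    # -- overlap -----------------------------------------------------------
    log.info("stage overlap: RNA/protein call overlap per (group, time)")
    rows = []
    for g in (ga, gb):
        for t in sim.sheet.times(g)[1:]:
            res = cross_layer_overlap(de["rna"], de["protein"], sim.ortholog_map, g, t)
            rows.append(
                {"group": g, "time": t, "n_rna": res.n_rna,
                 "n_protein": res.n_protein, "n_overlap": res.n_overlap}
            )
    overlap = pd.DataFrame(rows)
    write_table(overlap, outdir / "overlap.tsv", index=False)
    record("overlap", "overlap", outdir / "overlap.tsv", len(overlap))

    # -- enrich ------------------------------------------------------------
    log.info("stage enrich: archetype-set over-representation of flagged pairs")
    archetype_sets = GeneSetCollection(
        sets={
            f"archetype_{name}": frozenset(sim.truth.features_of(name))
            for name in sorted(sim.truth.labels.unique())
        },
        descriptions={},
    )
    write_gmt(archetype_sets, outdir / "archetype_sets.gmt")
    prot = scores["protein"]
    flagged = set(prot.loc[prot["flagged"], "feature_a"])
    universe = set(prot["feature_a"])
    enr = fisher_enrichment(flagged, archetype_sets, universe)
    write_table(enr, outdir / "enrichment.tsv", index=False)
    record("enrich", "enrichment", outdir / "enrichment.tsv", len(enr))

    # -- recovery summary --------------------------------------------------
    auroc = truth_auroc(
        prot.set_index("feature_a")["score"], sim.truth, positive="divergent"
    )
    manifest["summary"] = {
        "divergent_score_auroc_protein": float(auroc),
        "score_cutoff_protein": float(prot.attrs["cutoff"]),
        "n_flagged_protein": int(prot["flagged"].sum()),
    }

    with open(outdir / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    log.info("run complete: %s", outdir / "manifest.yaml")
    return manifest
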