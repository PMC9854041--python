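"""End-to-end orchestration: simulate -> windows -> partition -> eDMR ->
sRNA classification -> permutation -> variant summaries, from one config."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .genome import GenomeSpec
from .intervals import IntervalSet
from .io import bed_to_intervals
from .simulate import (
    CONTEXTS,
    ECOTYPES,
    STAGES,
    SimulationConfig,
    simulate_dataset,
    write_dataset,
)
from .windows import WindowCriteria, compute_window_methylation
from .regions import (
    RegionLabel,
    build_validity_matrix,
    combine_context_regions,
    label_intervals,
    partition_regions,
)
from .edmr import (
    call_edmrs,
    classify_edmr_features,
    compute_deltas,
    feature_class_counts,
    stage_consistent_edmrs,
)
from .srna import classify_e24src, test_differential_expression
from .enrichment import permutation_test
from .variants import (
    count_snps_per_window,
    hot_coverage,
    snp_window_percentages,
    substitution_zscore,
    sv_methylation_summary,
)

logger = logging.getLogger(__name__)

WINDOW_KEY = ["chrom", "start", "end", "context"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "seed" not in cfg:
        raise ValueError("config is missing required field 'seed'")
    return cfg


def run_pipeline(config_path: str | Path, outdir: str | Path | None = None) -> dict:
    """Run every stage; returns the manifest (also written as manifest.json)."""
    config_path = Path(config_path)
    cfg = load_config(config_path)
    seed = int(cfg["seed"])
    outdir = Path(outdir or cfg.get("outdir", "ecomethyl_out"))
    outdir.mkdir(parents=True, exist_ok=True)

    genome = (
        GenomeSpec.from_dict(cfg["genome"]) if "genome" in cfg else GenomeSpec.default_toy()
    )
    sim_cfg = SimulationConfig.from_dict({**cfg.get("simulation", {}), "seed": seed})
    wc = cfg.get("windows", {})
    criteria = WindowCriteria(
        window_size=int(wc.get("window_size", 50)),
        min_sites=int(wc.get("min_sites", 3)),
        min_reads=int(wc.get("min_reads", 10)),
    )
    min_eco_valid = int(cfg.get("partition", {}).get("min_ecotype_valid", 1))
    k_sd = float(cfg.get("edmr", {}).get("k", 1.0))
    srna_cfg = cfg.get("srna", {})
    fdr = float(srna_cfg.get("fdr", 0.05))
    fc = float(srna_cfg.get("fc", 2.0))
    perm_cfg = cfg.get("permutation", {})
    n_perm = int(perm_cfg.get("n_perm", 200))

    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config_path": str(config_path),
        "config_sha256": hashlib.sha256(config_path.read_bytes()).hexdigest(),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    def record(stage: str, artifacts: dict[str, str]) -> None:
        manifest["stages"][stage] = artifacts

    def guard(stage: str, written: list[Path], exc: Exception) -> None:
        for p in written:
            if p.exists():
                p.rename(p.with_name(p.name + ".partial"))
        raise StageError(stage, exc) from exc

    # ---- simulate -------------------------------------------------------------
    try:
        ds = simulate_dataset(sim_cfg, genome)
        data_paths = write_dataset(ds, outdir / "data")
        record("simulate", data_paths)
    except Exception as exc:  # noqa: BLE001
        guard("simulate", [], exc)

    # ---- windows --------------------------------------------------------------
    written: list[Path] = []
    try:
        window_tables: dict[str, pd.DataFrame] = {}
        for sample, rep in ds.reports.items():
            window_tables[sample] = compute_window_methylation(
                rep, criteria, genome=genome, sample=sample
            )
        win_path = outdir / "windows.tsv"
        written.append(win_path)
        pd.concat(window_tables.values(), ignore_index=True).to_csv(
            win_path, sep="\t", index=False
        )
        record("windows", {"windows": str(win_path)})
    except Exception as exc:  # noqa: BLE001
        guard("windows", written, exc)

    # ---- partition ------------------------------------------------------------
    written = []
    try:
        col_samples = [f"Col_{s}" for s in STAGES]
        cvi_samples = [f"Cvi_{s}" for s in STAGES]
        validity = build_validity_matrix(window_tables)
        labeled = partition_regions(
            validity, col_samples, cvi_samples, min_ecotype_valid=min_eco_valid
        )
        part_path = outdir / "region_labels.tsv"
        written.append(part_path)
        labeled.to_csv(part_path, sep="\t", index=False)
        artifacts = {"labels": str(part_path)}
        region_sets: dict[tuple[str, str], IntervalSet] = {}
        for label in (RegionLabel.CR, RegionLabel.COL_SR):
            for context in CONTEXTS:
                ivs = label_intervals(labeled, label, context=context, genome=genome)
                region_sets[(label.value, context)] = ivs
                bed = outdir / f"{label.value}_{context}.bed"
                written.append(bed)
                with open(bed, "w") as fh:
                    for chrom, s, e in ivs:
                        fh.write(f"{chrom}\t{s}\t{e}\n")
                artifacts[f"{label.value}_{context}"] = str(bed)
        record("partition", artifacts)
    except Exception as exc:  # noqa: BLE001
        guard("partition", written, exc)

    # ---- eDMR -----------------------------------------------------------------
    written = []
    try:
        cr_keys = labeled.loc[labeled["label"] == RegionLabel.CR.value, WINDOW_KEY]
        all_deltas = []
        for stage in STAGES:
            d = compute_deltas(
                window_tables[f"Col_{stage}"],
                window_tables[f"Cvi_{stage}"],
                stage,
                restrict_to=cr_keys,
            )
            all_deltas.append(d)
        deltas = pd.concat(all_deltas, ignore_index=True)
        calls, thresholds = call_edmrs(deltas, k=k_sd)
        consistent = stage_consistent_edmrs(calls, stages=STAGES)

        genes_set = bed_to_intervals(ds.annotations.genes, genome)
        tes_set = bed_to_intervals(ds.annotations.tes, genome)
        classified = classify_edmr_features(calls, genes_set, tes_set)
        consistent_cls = classify_edmr_features(
            consistent.assign(stage="R&G", delta=0.0), genes_set, tes_set
        )
        summary_rows = []
        for (context, stage), grp in pd.concat([classified, consistent_cls]).groupby(
            ["context", "stage"], sort=True
        ):
            counts = feature_class_counts(grp)
            for feature_class, n in counts.items():
                summary_rows.append(
                    {"context": context, "stage": stage,
                     "feature_class": feature_class, "n_windows": int(n)}
                )
        edmr_bed = outdir / "edmrs.bed"
        written.append(edmr_bed)
        with open(edmr_bed, "w") as fh:
            for r in calls.itertuples():
                score = int(round(abs(r.delta) * 1000))
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{r.direction}:{r.context}:{r.stage}"
                    f"\t{score}\t.\n"
                )
        paths = {
            "edmr_bed": str(edmr_bed),
            "edmr_calls": str(outdir / "edmr_calls.tsv"),
            "edmr_thresholds": str(outdir / "edmr_thresholds.tsv"),
            "edmr_consistent": str(outdir / "edmr_consistent.tsv"),
            "edmr_summary": str(outdir / "edmr_feature_summary.tsv"),
        }
        written += [Path(p) for p in paths.values()]
        calls.to_csv(paths["edmr_calls"], sep="\t", index=False)
        thresholds.to_csv(paths["edmr_thresholds"], sep="\t", index=False)
        consistent.to_csv(paths["edmr_consistent"], sep="\t", index=False)
        pd.DataFrame(summary_rows).to_csv(paths["edmr_summary"], sep="\t", index=False)
        record("edmr", paths)
    except Exception as exc:  # noqa: BLE001
        guard("edmr", written, exc)

    # ---- sRNA classification --------------------------------------------------
    written = []
    try:
        reps = range(1, sim_cfg.n_replicates + 1)
        stage_results = {}
        for stage in STAGES:
            ga = [f"Col_{stage}_r{i}" for i in reps]
            gb = [f"Cvi_{stage}_r{i}" for i in reps]
            stage_results[stage] = test_differential_expression(ds.counts, ga, gb)
        classes = classify_e24src(stage_results, fdr=fdr, fc=fc, stages=STAGES)
        srna_path = outdir / "e24src_classes.tsv"
        written.append(srna_path)
        classes.to_csv(srna_path, sep="\t")
        record("srna", {"classes": str(srna_path)})
    except Exception as exc:  # noqa: BLE001
        guard("srna", written, exc)

    # ---- permutation: stage-consistent eDMRs vs ecotype-consistent clusters ---
    written = []
    try:
        edmr_set = IntervalSet(
            [(r.chrom, int(r.start), int(r.end)) for r in consistent.itertuples()],
            genome=genome,
        )
        e_ids = classes.index[classes["class"].isin(["e24sRC_Col", "e24sRC_Cvi"])]
        cl = ds.clusters.set_index("cluster_id").loc[
            [i for i in e_ids if i in ds.clusters["cluster_id"].values]
        ]
        cluster_set = IntervalSet(
            [(r.chrom, int(r.start), int(r.end)) for r in cl.itertuples()], genome=genome
        )
        perm = permutation_test(
            cluster_set, edmr_set, genome,
            n_perm=n_perm,
            alternative=perm_cfg.get("alternative", "greater"),
            seed=seed,
        )
        perm_path = outdir / "permutation.json"
        written.append(perm_path)
        perm_path.write_text(json.dumps(perm.to_dict(), indent=1))
        record("permutation", {"result": str(perm_path)})
    except Exception as exc:  # noqa: BLE001
        guard("permutation", written, exc)

    # ---- variant summaries ----------------------------------------------------
    written = []
    try:
        rep_sample = f"{ECOTYPES[0]}_{STAGES[0]}"  # Col FH is the representative
        rep_windows = window_tables[rep_sample].merge(
            labeled[WINDOW_KEY + ["label"]], on=WINDOW_KEY
        )
        colsr = rep_windows[
            (rep_windows["label"] == RegionLabel.COL_SR.value)
        ]
        colsr_counts = count_snps_per_window(ds.annotations.snps, colsr)
        table2 = snp_window_percentages(colsr_counts)

        analyzed = rep_windows[
            rep_windows["label"].isin([RegionLabel.CR.value, RegionLabel.COL_SR.value])
            & rep_windows["valid"]
        ]
        subz = substitution_zscore(analyzed, ds.annotations.snps)

        sv_rows = []
        for stage in STAGES:
            w = window_tables[f"Col_{stage}"].assign(sample=f"Col_{stage}")
            sv_rows.append(sv_methylation_summary(ds.annotations.svs, w))
        sv_summary = pd.concat(sv_rows, ignore_index=True)

        hot_set = bed_to_intervals(ds.annotations.hot, genome)
        feature_sets = {
            f"SV_{cat}": IntervalSet(
                [(r.chrom, int(r.start), int(r.end)) for r in sub.itertuples()], genome=genome
            )
            for cat, sub in ds.annotations.svs.groupby("category")
        }
        feature_sets["CR_union"] = combine_context_regions(
            {c: region_sets[("CR", c)] for c in CONTEXTS}, "union"
        )
        feature_sets["COL_SR_union"] = combine_context_regions(
            {c: region_sets[("COL_SR", c)] for c in CONTEXTS}, "union"
        )
        feature_sets["COL_SR_intersection"] = combine_context_regions(
            {c: region_sets[("COL_SR", c)] for c in CONTEXTS}, "intersection"
        )
        feature_sets["24sRC"] = bed_to_intervals(ds.clusters, genome)
        hot_cov = hot_coverage(hot_set, feature_sets)

        paths = {
            "snp_windows": str(outdir / "colsr_snp_windows.tsv"),
            "substitution_z": str(outdir / "substitution_zscores.tsv"),
            "sv_methylation": str(outdir / "sv_methylation.tsv"),
            "hot_coverage": str(outdir / "hot_coverage.tsv"),
        }
        written += [Path(p) for p in paths.values()]
        table2.to_csv(paths["snp_windows"], sep="\t", index=False)
        subz.to_csv(paths["substitution_z"], sep="\t", index=False)
        sv_summary.to_csv(paths["sv_methylation"], sep="\t", index=False)
        hot_cov.to_csv(paths["hot_coverage"], sep="\t", index=False)
        record("variants", paths)
    except Exception as exc:  # noqa: BLE001
        guard("variants", written, exc)

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    for stage, artifacts in manifest["stages"].items():
        for name, p in artifacts.items():
            if not Path(p).exists():
                raise StageError(stage, FileNotFoundError(p))
    logger.info("pipeline complete: %s", manifest_path)
    return manifest
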