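"""Synthetic two-ecotype, three-stage seed dataset generator.

Emits everything the downstream stages consume — per-cytosine reports for
2 ecotypes x 3 stages, gene/TE annotations, SNP/SV/HOT tracks, 24-nt
cluster intervals with a replicated count matrix — together with a
machine-readable truth table of every planted effect, so recovery can be
scored without external data.

Design notes
------------
* Ecotype-specific regions are emulated purely as coverage dropout (Cvi
  depth forced to 0 over planted loci); the pipeline only ever observes
  mappability through coverage.
* Planted eDMR windows override the stratum baseline with a symmetric pair
  (base + delta/2 in the hyper ecotype, base - delta/2 in the other), held
  constant across stages so stage-consistency is recoverable.
* All randomness flows from per-component child generators derived from the
  single config seed, so outputs are byte-identical across reruns and
  components can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeSpec
from .intervals import IntervalSet
from . import io as eio

ECOTYPES = ("Col", "Cvi")
STAGES = ("FH", "AR", "GS")
CONTEXTS = ("CG", "CHG", "CHH")

SUBSTITUTION_CODES = tuple(
    a + b for a in "ACGT" for b in "ACGT" if a != b
)

_TRINUC = {"CG": "CGA", "CHG": "CAG", "CHH": "CAT"}
_SITE_OFFSET = {"CG": 3, "CHG": 7, "CHH": 1}

# rng stream tags (stable across versions)
_T_GENES, _T_TES, _T_DROPOUT, _T_EDMR, _T_SNP, _T_SV, _T_HOT = 1, 2, 3, 4, 5, 6, 7
_T_CLUSTERS, _T_COUNTS, _T_DEPTH = 8, 9, 10


@dataclass
class SimulationConfig:
    seed: int = 0
    window_size: int = 50
    # site grid spacing per context (bp); dense enough that full windows
    # always hold >= min_sites sites
    site_spacing: dict = field(default_factory=lambda: {"CG": 10, "CHG": 10, "CHH": 6})
    # baseline true methylation per stratum x context
    baseline: dict = field(
        default_factory=lambda: {
            "gene": {"CG": 0.45, "CHG": 0.08, "CHH": 0.05},
            "te": {"CG": 0.80, "CHG": 0.50, "CHH": 0.30},
            "igr": {"CG": 0.20, "CHG": 0.10, "CHH": 0.08},
        }
    )
    cvi_gene_cg_offset: float = 0.15  # Cvi genic CG sits this far below Col
    ar_noncg_gain: float = 0.08       # CHG/CHH gain at the AR stage, both ecotypes
    # planted eDMRs
    n_edmr_per_context: int = 30
    edmr_delta: float = 0.40
    edmr_base_fraction: float = 0.50
    edmr_hyper_fraction: float = 0.5
    # coverage dropout (Cvi-only) -> Col SR
    dropout_fraction: float = 0.02
    dropout_length: int = 500
    # SNPs
    snp_density: float = 0.002
    substitution_weights: dict = field(
        default_factory=lambda: {c: 1.0 for c in SUBSTITUTION_CODES}
    )
    # annotations
    n_genes: int = 120
    gene_length: int = 2000
    allow_gene_overlap: bool = False
    n_tes: int = 80
    te_length: int = 1000
    te_pericentromere_weight: float = 0.8
    # SVs / HOT
    n_svs: int = 30
    sv_length_min: int = 500
    sv_length_max: int = 5000
    sv_category_weights: dict = field(
        default_factory=lambda: {c: 1.0 for c in
                                 ("DEL", "INS", "DUP", "BRK", "INV", "SEQ", "UNCLASSIFIED")}
    )
    n_hot: int = 10
    hot_length: int = 5000
    # 24-nt clusters
    n_clusters: int = 150
    cluster_length: int = 200
    n_coupled_clusters: int = 60
    cluster_mean: float = 200.0
    cluster_dispersion: float = 0.1
    cluster_fold_change: float = 8.0
    n_replicates: int = 3
    stage_factors: dict = field(default_factory=lambda: {"FH": 1.0, "AR": 1.0, "GS": 0.8})
    # read depth: negative binomial with a floor
    depth_mean: float = 30.0
    depth_shape: float = 10.0
    depth_floor: int = 10

    def validate(self) -> None:
        def frac(name: str, v: float) -> None:
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

        for stratum, ctx_map in self.baseline.items():
            for ctx, v in ctx_map.items():
                frac(f"baseline[{stratum}][{ctx}]", v)
                if ctx != "CG":
                    frac(f"baseline[{stratum}][{ctx}]+ar_noncg_gain", v + self.ar_noncg_gain)
        frac("cvi_gene_cg_offset result",
             self.baseline["gene"]["CG"] - self.cvi_gene_cg_offset)
        frac("edmr_base_fraction+delta/2", self.edmr_base_fraction + self.edmr_delta / 2)
        frac("edmr_base_fraction-delta/2", self.edmr_base_fraction - self.edmr_delta / 2)
        frac("edmr_hyper_fraction", self.edmr_hyper_fraction)
        frac("dropout_fraction", self.dropout_fraction)
        frac("te_pericentromere_weight", self.te_pericentromere_weight)
        if not (0.0 <= self.snp_density <= 1.0):
            raise ValueError("snp_density outside [0, 1]")
        if self.cluster_dispersion <= 0:
            raise ValueError("cluster_dispersion must be positive")
        if self.cluster_fold_change < 1:
            raise ValueError("cluster_fold_change must be >= 1")
        if self.depth_floor < 0 or self.depth_mean <= 0 or self.depth_shape <= 0:
            raise ValueError("invalid depth model parameters")
        if self.sv_length_min > self.sv_length_max:
            raise ValueError("sv_length_min exceeds sv_length_max")
        if self.n_coupled_clusters > self.n_clusters:
            raise ValueError("n_coupled_clusters exceeds n_clusters")

    def _rng(self, *tags: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, *tags])

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# placement helpers
# ---------------------------------------------------------------------------

def _place_intervals(
    n: int,
    length_fn,
    genome: GenomeSpec,
    rng: np.random.Generator,
    allow_overlap: bool,
    within: dict[str, tuple[int, int]] | None = None,
    max_tries: int = 2000,
) -> list[tuple[str, int, int]]:
    chroms = genome.chroms
    sizes = np.array([genome.chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    placed: list[tuple[str, int, int]] = []
    for _ in range(n):
        length = int(length_fn(rng))
        for _try in range(max_tries):
            chrom = chroms[int(rng.choice(len(chroms), p=probs))]
            if within is not None:
                lo, hi = within.get(chrom, (0, genome.chrom_sizes[chrom]))
            else:
                lo, hi = 0, genome.chrom_sizes[chrom]
            if hi - lo < length:
                continue
            start = int(rng.integers(lo, hi - length + 1))
            end = start + length
            if not allow_overlap and any(
                c == chrom and s < end and start < e for c, s, e in placed
            ):
                continue
            placed.append((chrom, start, end))
            break
        else:
            raise RuntimeError(f"could not place interval of length {length}")
    return placed


# ---------------------------------------------------------------------------
# annotations, variant tracks
# ---------------------------------------------------------------------------

@dataclass
class Annotations:
    genes: pd.DataFrame
    tes: pd.DataFrame
    snps: pd.DataFrame
    svs: pd.DataFrame
    hot: pd.DataFrame


def simulate_annotations(config: SimulationConfig, genome: GenomeSpec) -> Annotations:
    """Genes on chromosome arms, TEs biased into pericentromeres, plus SNP,
    SV and HOT tracks."""
    config.validate()

    rng = config._rng(_T_GENES)
    genes = _place_intervals(
        config.n_genes, lambda r: config.gene_length, genome, rng,
        allow_overlap=config.allow_gene_overlap,
    )
    genes_df = pd.DataFrame(
        [
            {"feature_id": f"gene{i:04d}", "chrom": c, "start": s, "end": e, "kind": "gene"}
            for i, (c, s, e) in enumerate(sorted(genes))
        ]
    )

    rng = config._rng(_T_TES)
    tes: list[tuple[str, int, int]] = []
    for _ in range(config.n_tes):
        in_peri = rng.random() < config.te_pericentromere_weight and genome.pericentromeres
        within = genome.pericentromeres if in_peri else None
        tes.extend(
            _place_intervals(1, lambda r: config.te_length, genome, rng,
                             allow_overlap=True, within=within)
        )
    tes_df = pd.DataFrame(
        [
            {"feature_id": f"te{i:04d}", "chrom": c, "start": s, "end": e,
             "kind": "transposable_element"}
            for i, (c, s, e) in enumerate(sorted(tes))
        ]
    )

    # SNPs: per-chromosome Binomial(L, density) positions, weighted codes
    rng = config._rng(_T_SNP)
    codes = list(config.substitution_weights)
    w = np.array([config.substitution_weights[c] for c in codes], dtype=float)
    snp_rows = []
    if config.snp_density > 0:
        w = w / w.sum()
        for chrom, size in genome.chrom_sizes.items():
            n_snp = int(rng.binomial(size, config.snp_density))
            pos0 = np.sort(rng.choice(size, size=n_snp, replace=False))
            subs = rng.choice(codes, size=n_snp, p=w)
            for p, code in zip(pos0, subs):
                snp_rows.append(
                    {"chrom": chrom, "pos": int(p) + 1,
                     "col_base": code[0], "cvi_base": code[1], "substitution": code}
                )
    snps_df = pd.DataFrame(
        snp_rows, columns=["chrom", "pos", "col_base", "cvi_base", "substitution"]
    )

    rng = config._rng(_T_SV)
    cats = list(config.sv_category_weights)
    cw = np.array([config.sv_category_weights[c] for c in cats], dtype=float)
    cw = cw / cw.sum()
    sv_cats = rng.choice(cats, size=config.n_svs, p=cw)
    sv_ivs = _place_intervals(
        config.n_svs,
        lambda r: int(r.integers(config.sv_length_min, config.sv_length_max + 1)),
        genome, rng, allow_overlap=True,
    )
    svs_df = pd.DataFrame(
        [
            {"chrom": c, "start": s, "end": e, "category": cat}
            for (c, s, e), cat in zip(sv_ivs, sv_cats)
        ]
    ).sort_values(["chrom", "start"]).reset_index(drop=True)

    rng = config._rng(_T_HOT)
    hot_ivs = _place_intervals(
        config.n_hot, lambda r: config.hot_length, genome, rng, allow_overlap=False,
    )
    hot_df = pd.DataFrame(
        [{"chrom": c, "start": s, "end": e} for c, s, e in sorted(hot_ivs)]
    )
    return Annotations(genes=genes_df, tes=tes_df, snps=snps_df, svs=svs_df, hot=hot_df)


# ---------------------------------------------------------------------------
# planted effects
# ---------------------------------------------------------------------------

def _plant_loci(
    config: SimulationConfig, genome: GenomeSpec, ann: Annotations
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Choose dropout loci and planted eDMR windows (outside features/dropout)."""
    ws = config.window_size
    rng = config._rng(_T_DROPOUT)
    dropout_rows = []
    if config.dropout_fraction > 0:
        n_regions = max(
            1, int(round(config.dropout_fraction * genome.total_bp / config.dropout_length))
        )
        for chrom, s, e in _place_intervals(
            n_regions, lambda r: config.dropout_length, genome, rng, allow_overlap=False,
        ):
            # snap to window grid so SR truth aligns with window boundaries
            s = (s // ws) * ws
            e = min(((e + ws - 1) // ws) * ws, genome.chrom_sizes[chrom])
            dropout_rows.append({"chrom": chrom, "start": s, "end": e})
    dropout = pd.DataFrame(dropout_rows, columns=["chrom", "start", "end"])

    blocked = IntervalSet(
        [(r.chrom, r.start, r.end) for r in ann.genes.itertuples()]
        + [(r.chrom, r.start, r.end) for r in ann.tes.itertuples()]
        + [(r.chrom, int(r.start), int(r.end)) for r in dropout.itertuples()]
    )
    blocked = blocked.merge() if len(blocked) else blocked

    eligible = []
    for chrom, size in genome.chrom_sizes.items():
        starts = np.arange(0, size - ws + 1, ws, dtype=np.int64)
        free = ~blocked.overlaps_point_mask(chrom, starts, starts + ws)
        eligible.extend((chrom, int(s)) for s in starts[free])

    rng = config._rng(_T_EDMR)
    need = config.n_edmr_per_context * len(CONTEXTS)
    if need > len(eligible):
        raise ValueError(
            f"cannot plant {need} eDMR windows: only {len(eligible)} eligible windows"
        )
    pick = rng.choice(len(eligible), size=need, replace=False)
    edmr_rows = []
    idx = 0
    for context in CONTEXTS:
        for _ in range(config.n_edmr_per_context):
            chrom, start = eligible[int(pick[idx])]
            direction = "hyper" if rng.random() < config.edmr_hyper_fraction else "hypo"
            edmr_rows.append(
                {
                    "chrom": chrom, "start": start, "end": start + ws,
                    "context": context, "direction": direction,
                    "delta": config.edmr_delta if direction == "hyper" else -config.edmr_delta,
                }
            )
            idx += 1
    edmrs = pd.DataFrame(edmr_rows).sort_values(["context", "chrom", "start"]).reset_index(drop=True)
    return dropout, edmrs


# ---------------------------------------------------------------------------
# cytosine reports
# ---------------------------------------------------------------------------

def _site_grid(config: SimulationConfig, genome: GenomeSpec) -> pd.DataFrame:
    """Deterministic site positions per context (shared across all samples)."""
    rows = []
    for chrom, size in genome.chrom_sizes.items():
        for context in CONTEXTS:
            spacing = int(config.site_spacing[context])
            pos0 = np.arange(_SITE_OFFSET[context], size, spacing, dtype=np.int64)
            df = pd.DataFrame({"chrom": chrom, "pos": pos0 + 1, "context": context})
            df["strand"] = np.where(np.arange(len(df)) % 2 == 0, "+", "-")
            rows.append(df)
    sites = pd.concat(rows, ignore_index=True)
    sites["trinucleotide"] = sites["context"].map(_TRINUC)
    return sites.sort_values(["chrom", "pos"]).reset_index(drop=True)


def _site_strata(
    sites: pd.DataFrame, ann: Annotations, edmrs: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site gene/TE membership and planted-eDMR sign (computed once).

    Returns (in_gene, in_te, planted) where planted is +1 over Col-hyper
    windows, -1 over Col-hypo windows, 0 elsewhere (context-matched).
    """
    gene_set = IntervalSet(
        [(r.chrom, r.start, r.end) for r in ann.genes.itertuples()]
    ).merge() if len(ann.genes) else IntervalSet()
    te_set = IntervalSet(
        [(r.chrom, r.start, r.end) for r in ann.tes.itertuples()]
    ).merge() if len(ann.tes) else IntervalSet()

    pos0_all = sites["pos"].to_numpy() - 1
    in_gene = np.zeros(len(sites), dtype=bool)
    in_te = np.zeros(len(sites), dtype=bool)
    planted = np.zeros(len(sites), dtype=np.int8)
    for chrom, grp in sites.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos0 = pos0_all[idx]
        in_gene[idx] = gene_set.overlaps_point_mask(chrom, pos0, pos0 + 1)
        in_te[idx] = te_set.overlaps_point_mask(chrom, pos0, pos0 + 1)
    for context in CONTEXTS:
        for direction, sign in (("hyper", 1), ("hypo", -1)):
            sel = edmrs[(edmrs["context"] == context) & (edmrs["direction"] == direction)]
            if sel.empty:
                continue
            pset = IntervalSet(
                [(r.chrom, r.start, r.end) for r in sel.itertuples()]
            ).merge()
            for chrom, grp in sites[sites["context"] == context].groupby("chrom", sort=False):
                idx = grp.index.to_numpy()
                pos0 = pos0_all[idx]
                hit = pset.overlaps_point_mask(chrom, pos0, pos0 + 1)
                planted[idx[hit]] = sign
    return in_gene, in_te, planted


def _true_fractions(
    sites: pd.DataFrame,
    config: SimulationConfig,
    strata: tuple[np.ndarray, np.ndarray, np.ndarray],
    ecotype: str,
    stage: str,
) -> np.ndarray:
    in_gene, in_te, planted = strata
    frac = np.empty(len(sites), dtype=float)
    context_arr = sites["context"].to_numpy()
    for context in CONTEXTS:
        cmask = context_arr == context
        base = np.full(int(cmask.sum()), config.baseline["igr"][context])
        base[in_gene[cmask]] = config.baseline["gene"][context]
        if ecotype == "Cvi" and context == "CG":
            base[in_gene[cmask]] -= config.cvi_gene_cg_offset
        base[in_te[cmask]] = config.baseline["te"][context]
        if stage == "AR" and context != "CG":
            base = base + config.ar_noncg_gain
        frac[cmask] = base
    half = config.edmr_delta / 2
    eco_sign = 1.0 if ecotype == "Col" else -1.0
    hit = planted != 0
    frac[hit] = config.edmr_base_fraction + eco_sign * planted[hit] * half
    return frac


def simulate_cytosine_reports(
    config: SimulationConfig,
    genome: GenomeSpec,
    annotations: Annotations | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Generate the six per-sample CX reports plus the truth table.

    Returns (reports keyed by "Ecotype_STAGE", truth table). Per-site
    methylated counts are binomial around the stratum's true fraction; depth
    is negative binomial floored at ``depth_floor``; Cvi depth is zero over
    dropout loci.
    """
    config.validate()
    ann = annotations if annotations is not None else simulate_annotations(config, genome)
    dropout, edmrs = _plant_loci(config, genome, ann)
    sites = _site_grid(config, genome)

    dropout_set = IntervalSet(
        [(r.chrom, int(r.start), int(r.end)) for r in dropout.itertuples()]
    )
    dropout_set = dropout_set.merge() if len(dropout_set) else dropout_set
    pos0 = sites["pos"].to_numpy() - 1
    in_dropout = np.zeros(len(sites), dtype=bool)
    for chrom, grp in sites.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        in_dropout[idx] = dropout_set.overlaps_point_mask(chrom, pos0[idx], pos0[idx] + 1)

    strata = _site_strata(sites, ann, edmrs)
    reports: dict[str, pd.DataFrame] = {}
    r_shape = config.depth_shape
    p_nb = r_shape / (r_shape + config.depth_mean)
    for ei, ecotype in enumerate(ECOTYPES):
        for si, stage in enumerate(STAGES):
            rng = config._rng(_T_DEPTH, ei, si)
            depth = rng.negative_binomial(r_shape, p_nb, size=len(sites))
            depth = np.maximum(depth, config.depth_floor)
            if ecotype == "Cvi":
                depth = np.where(in_dropout, 0, depth)
            p_true = _true_fractions(sites, config, strata, ecotype, stage)
            meth = rng.binomial(depth, p_true)
            rep = sites.copy()
            rep["meth_count"] = meth
            rep["unmeth_count"] = depth - meth
            reports[f"{ecotype}_{stage}"] = rep[eio.CX_COLUMNS]

    truth_rows = [
        {"kind": "edmr", "chrom": r.chrom, "start": r.start, "end": r.end,
         "context": r.context, "name": r.direction, "value": r.delta}
        for r in edmrs.itertuples()
    ] + [
        {"kind": "dropout", "chrom": r.chrom, "start": int(r.start), "end": int(r.end),
         "context": "*", "name": "cvi_zero_coverage", "value": 0.0}
        for r in dropout.itertuples()
    ]
    truth = pd.DataFrame(
        truth_rows, columns=["kind", "chrom", "start", "end", "context", "name", "value"]
    )
    return reports, truth


# ---------------------------------------------------------------------------
# 24-nt small RNA clusters
# ---------------------------------------------------------------------------

def simulate_srna_counts(
    config: SimulationConfig,
    genome: GenomeSpec,
    edmr_truth: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cluster BED + negative-binomial count matrix + per-cluster truth.

    The first ``n_coupled_clusters`` clusters sit on planted eDMR windows
    (when supplied) with an ecotype fold-change whose direction matches the
    planted methylation difference (hyper -> Col-up). Remaining clusters are
    placed uniformly with no ecotype effect.
    """
    config.validate()
    rng = config._rng(_T_CLUSTERS)
    rows = []
    coupled_pool = (
        edmr_truth[edmr_truth["kind"] == "edmr"].reset_index(drop=True)
        if edmr_truth is not None
        else pd.DataFrame(columns=["chrom", "start", "end", "name"])
    )
    n_coupled = min(config.n_coupled_clusters, len(coupled_pool))
    order = rng.permutation(len(coupled_pool))[:n_coupled] if n_coupled else []
    for i, j in enumerate(order):
        locus = coupled_pool.iloc[int(j)]
        mid = (int(locus["start"]) + int(locus["end"])) // 2
        half = config.cluster_length // 2
        start = max(0, mid - half)
        end = min(genome.chrom_sizes[locus["chrom"]], start + config.cluster_length)
        direction = "Col" if locus["name"] == "hyper" else "Cvi"
        rows.append(
            {"chrom": locus["chrom"], "start": start, "end": end,
             "cluster_id": f"c{i:05d}", "up_ecotype": direction}
        )
    n_free = config.n_clusters - len(rows)
    for chrom, s, e in _place_intervals(
        n_free, lambda r: config.cluster_length, genome, rng, allow_overlap=False,
    ):
        rows.append(
            {"chrom": chrom, "start": s, "end": e,
             "cluster_id": f"c{len(rows):05d}", "up_ecotype": "none"}
        )
    clusters = pd.DataFrame(rows)

    rng = config._rng(_T_COUNTS)
    r_nb = 1.0 / config.cluster_dispersion
    sqrt_fc = np.sqrt(config.cluster_fold_change)
    data: dict[str, np.ndarray] = {}
    for ecotype in ECOTYPES:
        for stage in STAGES:
            stage_mu = config.cluster_mean * config.stage_factors[stage]
            mult = np.ones(len(clusters))
            up = clusters["up_ecotype"].to_numpy()
            mult[up == ecotype] = sqrt_fc
            mult[(up != ecotype) & (up != "none")] = 1.0 / sqrt_fc
            mu = stage_mu * mult
            for rep in range(1, config.n_replicates + 1):
                p = r_nb / (r_nb + mu)
                data[f"{ecotype}_{stage}_r{rep}"] = rng.negative_binomial(r_nb, p)
    counts = pd.DataFrame(data, index=clusters["cluster_id"])
    counts.index.name = "cluster_id"

    truth = clusters[["cluster_id", "chrom", "start", "end", "up_ecotype"]].copy()
    truth["true_class"] = truth["up_ecotype"].map(
        {"Col": "e24sRC_Col", "Cvi": "e24sRC_Cvi", "none": "non_e24sRC"}
    )
    return clusters[["chrom", "start", "end", "cluster_id"]], counts, truth


# ---------------------------------------------------------------------------
# orchestration + serialization
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: GenomeSpec
    annotations: Annotations
    reports: dict[str, pd.DataFrame]
    clusters: pd.DataFrame
    counts: pd.DataFrame
    truth: pd.DataFrame  # unified: eDMRs + dropout + cluster classes


def simulate_dataset(config: SimulationConfig, genome: GenomeSpec | None = None) -> SyntheticDataset:
    """Generate the complete dataset in memory."""
    genome = genome or GenomeSpec.default_toy()
    config.validate()
    ann = simulate_annotations(config, genome)
    reports, meth_truth = simulate_cytosine_reports(config, genome, annotations=ann)
    clusters, counts, cluster_truth = simulate_srna_counts(config, genome, meth_truth)
    ct = cluster_truth.rename(columns={"true_class": "name"})
    ct["kind"] = "cluster"
    ct["context"] = "*"
    ct["value"] = 0.0
    truth = pd.concat(
        [meth_truth, ct[["kind", "chrom", "start", "end", "context", "name", "value"]]],
        ignore_index=True,
    )
    return SyntheticDataset(
        config=config, genome=genome, annotations=ann,
        reports=reports, clusters=clusters, counts=counts, truth=truth,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, str]:
    """Serialize every artifact as plain text; returns name -> path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def put(name: str, fname: str) -> Path:
        p = outdir / fname
        paths[name] = str(p)
        return p

    for sample, rep in ds.reports.items():
        eio.write_cx_report(rep, put(f"cx_{sample}", f"{sample}.CX_report.txt"))
    features = pd.concat([ds.annotations.genes, ds.annotations.tes], ignore_index=True)
    eio.write_gff3_features(features, put("features_gff3", "features.gff3"))
    bed = features.rename(columns={"feature_id": "name"})
    bed["score"] = 0
    bed["strand"] = "+"
    eio.write_bed(bed, put("features_bed", "features.bed"),
                  extra_cols=["name", "score", "strand"])
    ds.annotations.snps.to_csv(
        put("snps", "snps.tsv"), sep="\t", header=False, index=False,
        columns=["chrom", "pos", "col_base", "cvi_base"],
    )
    eio.write_bed(ds.annotations.svs, put("svs", "svs.bed"), extra_cols=["category"])
    eio.write_bed(ds.annotations.hot, put("hot", "hot.bed"))
    eio.write_bed(ds.clusters, put("clusters", "clusters.bed"), extra_cols=["cluster_id"])
    ds.counts.to_csv(put("counts", "cluster_counts.tsv"), sep="\t")
    ds.truth.to_csv(put("truth", "truth.tsv"), sep="\t", index=False)
    with open(put("genome", "genome.tsv"), "w") as fh:
        for chrom, size in ds.genome.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    return paths
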