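"""Ecotype-differential methylation calling over common-region windows.

For each stage and context, the per-window difference delta = Col - Cvi is
summarized by its mean m and population standard deviation sigma; windows
with delta strictly above m + k*sigma are hyper (Col-hypermethylated) and
strictly below m - k*sigma are hypo (Cvi-hypermethylated). Stage-consistent
calls ("maintained" regions) require the same direction at every stage.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .intervals import IntervalSet

logger = logging.getLogger(__name__)

WINDOW_KEY = ["chrom", "start", "end", "context"]

HYPER = "hyper"
HYPO = "hypo"

FEATURE_CLASSES = ("Gene", "Gene&TE", "TE", "IGR")

GBM_SECTIONS = ("col_only", "cvi_only", "mid_both", "high_both", "unassigned")


def compute_deltas(
    col_windows: pd.DataFrame,
    cvi_windows: pd.DataFrame,
    stage: str,
    restrict_to: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-window Col minus Cvi fraction, over windows valid in both samples.

    ``restrict_to`` optionally limits the join to a key frame (e.g. CR
    windows from the region partition). Windows present/valid in only one
    ecotype are dropped; the number dropped is logged.
    """
    a = col_windows.loc[col_windows["valid"], WINDOW_KEY + ["fraction"]]
    b = cvi_windows.loc[cvi_windows["valid"], WINDOW_KEY + ["fraction"]]
    merged = a.merge(b, on=WINDOW_KEY, how="outer", suffixes=("_col", "_cvi"))
    both = merged.dropna(subset=["fraction_col", "fraction_cvi"])
    n_dropped = len(merged) - len(both)
    if n_dropped:
        logger.info("compute_deltas(%s): excluded %d single-ecotype windows", stage, n_dropped)
    out = both[WINDOW_KEY].copy()
    out["stage"] = stage
    out["delta"] = both["fraction_col"].to_numpy() - both["fraction_cvi"].to_numpy()
    if restrict_to is not None:
        out = out.merge(restrict_to[WINDOW_KEY].drop_duplicates(), on=WINDOW_KEY, how="inner")
    return out.reset_index(drop=True)


def call_edmrs(
    deltas: pd.DataFrame,
    k: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the mean +/- k*sigma rule per (context, stage).

    Returns (calls, thresholds). sigma is the population SD (ddof=0); calls
    use strict inequalities. A zero sigma yields no calls with a warning.
    """
    calls = []
    thr_rows = []
    for (context, stage), grp in deltas.groupby(["context", "stage"], sort=True):
        d = grp["delta"].to_numpy(dtype=float)
        if len(d) < 2:
            raise ValueError(f"need >= 2 deltas for {context}/{stage}, got {len(d)}")
        m = float(np.mean(d))
        sigma = float(np.std(d, ddof=0))
        thr_rows.append(
            {"context": context, "stage": stage, "mean": m, "sd": sigma,
             "upper": m + k * sigma, "lower": m - k * sigma}
        )
        if sigma <= 1e-12:  # degenerate spread (identical deltas up to fp noise)
            logger.warning("call_edmrs: sigma=0 for %s/%s, no calls", context, stage)
            continue
        hyper = grp[d > m + k * sigma].copy()
        hyper["direction"] = HYPER
        hypo = grp[d < m - k * sigma].copy()
        hypo["direction"] = HYPO
        calls.append(hyper)
        calls.append(hypo)
    columns = WINDOW_KEY + ["stage", "delta", "direction"]
    if calls:
        out = pd.concat(calls, ignore_index=True)[columns]
    else:
        out = pd.DataFrame(columns=columns)
    out = out.sort_values(WINDOW_KEY + ["stage"]).reset_index(drop=True)
    return out, pd.DataFrame(thr_rows)


def stage_consistent_edmrs(calls: pd.DataFrame, stages: tuple[str, ...] = ("FH", "AR", "GS")) -> pd.DataFrame:
    """Windows called at every stage with an identical direction."""
    if len(stages) < 3:
        raise ValueError(f"three stage call sets required, got {len(stages)}")
    per_window = calls[calls["stage"].isin(stages)].groupby(
        WINDOW_KEY + ["direction"], sort=False
    )["stage"].nunique()
    keep = per_window[per_window == len(stages)].reset_index()
    return keep[WINDOW_KEY + ["direction"]].sort_values(WINDOW_KEY).reset_index(drop=True)


def _overlap_flags(df: pd.DataFrame, features: IntervalSet) -> np.ndarray:
    merged = features.merge()
    flags = np.zeros(len(df), dtype=bool)
    for chrom, grp in df.groupby("chrom", sort=False):
        mask = merged.overlaps_point_mask(
            chrom, grp["start"].to_numpy(), grp["end"].to_numpy()
        )
        flags[grp.index.to_numpy()] = mask
    return flags


def classify_edmr_features(
    edmrs: pd.DataFrame,
    genes: IntervalSet,
    tes: IntervalSet,
) -> pd.DataFrame:
    """Assign each eDMR window to Gene / Gene&TE / TE / IGR by >= 1 bp overlap."""
    out = edmrs.reset_index(drop=True).copy()
    in_gene = _overlap_flags(out, genes)
    in_te = _overlap_flags(out, tes)
    cls = np.where(
        in_gene & in_te, "Gene&TE",
        np.where(in_gene, "Gene", np.where(in_te, "TE", "IGR")),
    )
    out["feature_class"] = cls
    return out


def feature_class_counts(classified: pd.DataFrame) -> pd.Series:
    """Counts per feature class (all four classes present, plus Total)."""
    counts = classified["feature_class"].value_counts()
    out = pd.Series({c: int(counts.get(c, 0)) for c in FEATURE_CLASSES})
    out["Total"] = int(out.sum())
    return out


def section_gbm(
    gene_fractions: pd.DataFrame,
    hi: float = 0.6,
    lo: float = 0.2,
) -> pd.DataFrame:
    """Classify genes by their anchor-stage (Col, Cvi) methylation pair.

    ``gene_fractions`` needs feature_id, fraction_col, fraction_cvi (both
    from genes valid under the feature site rule in both ecotypes).
    """
    if hi <= lo:
        raise ValueError("hi threshold must exceed lo threshold")
    col = gene_fractions["fraction_col"].to_numpy(dtype=float)
    cvi = gene_fractions["fraction_cvi"].to_numpy(dtype=float)
    section = np.full(len(gene_fractions), "unassigned", dtype=object)
    section[(col >= hi) & (cvi >= hi)] = "high_both"
    section[(col > lo) & (col < hi) & (cvi > lo) & (cvi < hi)] = "mid_both"
    section[(col >= hi) & (cvi <= lo)] = "col_only"
    section[(cvi >= hi) & (col <= lo)] = "cvi_only"
    out = gene_fractions.copy()
    out["section"] = section
    return out
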