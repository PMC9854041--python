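"""Partition windows into common vs ecotype-specific regions.

A window is CR when it is valid in all six ecotype-by-stage samples; it is
Col-specific (COL_SR) when valid in at least ``min_ecotype_valid`` Col
samples and in no Cvi sample (and symmetrically for CVI_SR). MIXED and NONE
complete the partition so that every window carries exactly one label.
"""

from __future__ import annotations

from enum import Enum

import numpy as np
import pandas as pd

from .intervals import IntervalSet, merge_intervals  # noqa: F401  (re-export)


class RegionLabel(str, Enum):
    CR = "CR"
    COL_SR = "COL_SR"
    CVI_SR = "CVI_SR"
    MIXED = "MIXED"
    NONE = "NONE"


def classify_validity_pattern(
    col_flags: tuple[bool, ...],
    cvi_flags: tuple[bool, ...],
    min_ecotype_valid: int = 1,
) -> RegionLabel:
    """Label a single window from its per-ecotype validity flags."""
    n_col, n_cvi = sum(col_flags), sum(cvi_flags)
    if n_col == len(col_flags) and n_cvi == len(cvi_flags):
        return RegionLabel.CR
    if n_col == 0 and n_cvi == 0:
        return RegionLabel.NONE
    if n_cvi == 0 and n_col >= min_ecotype_valid:
        return RegionLabel.COL_SR
    if n_col == 0 and n_cvi >= min_ecotype_valid:
        return RegionLabel.CVI_SR
    return RegionLabel.MIXED


def partition_regions(
    validity: pd.DataFrame,
    col_samples: list[str],
    cvi_samples: list[str],
    min_ecotype_valid: int = 1,
) -> pd.DataFrame:
    """Vectorized labelling of a full validity matrix.

    ``validity`` holds the window key columns (chrom, start, end, context)
    plus one boolean column per sample. Missing sample columns raise.
    """
    for s in col_samples + cvi_samples:
        if s not in validity.columns:
            raise ValueError(f"missing sample column {s!r} in validity matrix")
    n_col = validity[col_samples].to_numpy(dtype=bool).sum(axis=1)
    n_cvi = validity[cvi_samples].to_numpy(dtype=bool).sum(axis=1)
    label = np.full(len(validity), RegionLabel.MIXED.value, dtype=object)
    label[(n_col == len(col_samples)) & (n_cvi == len(cvi_samples))] = RegionLabel.CR.value
    label[(n_col == 0) & (n_cvi == 0)] = RegionLabel.NONE.value
    label[(n_cvi == 0) & (n_col >= min_ecotype_valid)] = RegionLabel.COL_SR.value
    label[(n_col == 0) & (n_cvi >= min_ecotype_valid)] = RegionLabel.CVI_SR.value
    out = validity[["chrom", "start", "end", "context"]].copy()
    out["label"] = label
    return out


def build_validity_matrix(window_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pivot per-sample window tables into one boolean matrix.

    ``window_tables`` maps sample id -> output of compute_window_methylation.
    All tables must tile the same windows (use a genome-bound computation).
    """
    key = ["chrom", "start", "end", "context"]
    out: pd.DataFrame | None = None
    for sample, tbl in window_tables.items():
        piece = tbl[key + ["valid"]].rename(columns={"valid": sample})
        out = piece if out is None else out.merge(piece, on=key, how="outer")
    if out is None:
        raise ValueError("no window tables supplied")
    sample_cols = [c for c in out.columns if c not in key]
    out[sample_cols] = out[sample_cols].fillna(False).astype(bool)
    return out.sort_values(key).reset_index(drop=True)


def label_intervals(
    labeled: pd.DataFrame,
    label: RegionLabel | str,
    context: str | None = None,
    max_gap: int = 1,
    genome=None,
) -> IntervalSet:
    """Merged IntervalSet of all windows carrying one label (optionally one context)."""
    want = label.value if isinstance(label, RegionLabel) else label
    sel = labeled[labeled["label"] == want]
    if context is not None:
        sel = sel[sel["context"] == context]
    ivs = IntervalSet(
        list(zip(sel["chrom"], sel["start"].astype(int), sel["end"].astype(int))),
        genome=genome,
    )
    if len(ivs) == 0:
        return ivs
    return ivs.merge(max_gap=max_gap)


def combine_context_regions(
    per_context: dict[str, IntervalSet],
    mode: str = "union",
) -> IntervalSet:
    """Combine per-context region sets at base-pair level.

    union: loci covered by >= 1 context; intersection: loci covered by all.
    """
    if mode not in ("union", "intersection"):
        raise ValueError(f"unknown mode {mode!r}")
    if not per_context:
        raise ValueError("no context sets supplied")
    sets = list(per_context.values())
    out = sets[0].merge()
    for other in sets[1:]:
        out = out.union(other) if mode == "union" else out.intersect(other)
    return out
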