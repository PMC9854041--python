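"""Fractional methylation over fixed windows and annotated features.

A cytosine site qualifies when its read depth (methylated + unmethylated)
meets ``min_reads``. The window/feature level is the *unweighted mean* of the
qualifying per-site fractions — sites are averaged, counts are never pooled.
A window is valid when it holds at least ``min_sites`` qualifying sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeSpec
from .io import CONTEXTS, read_cx_report

__all__ = [
    "WindowCriteria",
    "read_cytosine_report",
    "compute_window_methylation",
    "compute_feature_methylation",
    "chromosomal_view_windows",
]

WINDOW_COLUMNS = ["chrom", "start", "end", "context", "n_qual_sites", "fraction", "valid"]


@dataclass(frozen=True)
class WindowCriteria:
    window_size: int = 50
    min_sites: int = 3
    min_reads: int = 10

    def __post_init__(self) -> None:
        for name in ("window_size", "min_sites", "min_reads"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


# 5-kb chromosomal-view variant of the 50-bp criteria
CHROMOSOMAL_VIEW = WindowCriteria(window_size=5000, min_sites=10, min_reads=10)


def read_cytosine_report(path) -> pd.DataFrame:
    """Alias for :func:`ecomethyl.io.read_cx_report` (validated parse)."""
    return read_cx_report(path)


def _qualify(sites: pd.DataFrame, min_reads: int) -> pd.DataFrame:
    depth = sites["meth_count"].to_numpy() + sites["unmeth_count"].to_numpy()
    qual = depth >= min_reads
    out = sites.loc[qual, ["chrom", "pos", "context"]].copy()
    with np.errstate(invalid="ignore"):
        out["site_fraction"] = (
            sites.loc[qual, "meth_count"].to_numpy() / depth[qual]
        )
    return out


def compute_window_methylation(
    sites: pd.DataFrame,
    criteria: WindowCriteria = WindowCriteria(),
    genome: GenomeSpec | None = None,
    sample: str | None = None,
) -> pd.DataFrame:
    """Tile chromosomes with non-overlapping windows and average site fractions.

    Parameters
    ----------
    sites
        CX-report frame (chrom, pos 1-based, strand, counts, context, ...).
        Strand is carried in the input but never enters the arithmetic.
    genome
        When given, every (window, context) tile of every chromosome is
        emitted, including empty ones (n_qual_sites=0, invalid). Otherwise
        only occupied tiles appear.
    """
    ws = criteria.window_size
    qual = _qualify(sites, criteria.min_reads)
    if len(qual):
        qual["start"] = ((qual["pos"] - 1) // ws) * ws
        grouped = (
            qual.groupby(["chrom", "start", "context"], sort=True)["site_fraction"]
            .agg(n_qual_sites="size", fraction="mean")
            .reset_index()
        )
    else:
        grouped = pd.DataFrame(
            {
                "chrom": pd.Series(dtype=str),
                "start": pd.Series(dtype=np.int64),
                "context": pd.Series(dtype=str),
                "n_qual_sites": pd.Series(dtype=np.int64),
                "fraction": pd.Series(dtype=float),
            }
        )

    if genome is not None:
        frames = []
        for chrom, size in genome.chrom_sizes.items():
            starts = np.arange(0, size, ws, dtype=np.int64)
            full = pd.MultiIndex.from_product(
                [[chrom], starts, list(CONTEXTS)], names=["chrom", "start", "context"]
            ).to_frame(index=False)
            frames.append(full)
        full = pd.concat(frames, ignore_index=True)
        grouped = full.merge(grouped, on=["chrom", "start", "context"], how="left")
        grouped["n_qual_sites"] = grouped["n_qual_sites"].fillna(0)

    grouped["n_qual_sites"] = grouped["n_qual_sites"].astype(np.int64)
    grouped["start"] = grouped["start"].astype(np.int64)
    grouped["end"] = grouped["start"] + ws
    if genome is not None:
        caps = grouped["chrom"].map(genome.chrom_sizes)
        grouped["end"] = np.minimum(grouped["end"], caps)
    grouped["valid"] = grouped["n_qual_sites"] >= criteria.min_sites
    if sample is not None:
        grouped["sample"] = sample
    cols = WINDOW_COLUMNS + (["sample"] if sample is not None else [])
    return grouped[cols].sort_values(["chrom", "start", "context"]).reset_index(drop=True)


def compute_feature_methylation(
    sites: pd.DataFrame,
    features: pd.DataFrame,
    min_sites: int = 5,
    min_reads: int = 10,
    sample: str | None = None,
) -> pd.DataFrame:
    """Mean qualifying-site fraction within each feature span, per context.

    ``features`` needs feature_id, chrom, start, end (0-based half-open) and
    optionally kind. Features may overlap; each is evaluated independently.
    """
    if (features["start"] < 0).any() or (features["end"] <= features["start"]).any():
        raise ValueError("feature with invalid coordinates")
    qual = _qualify(sites, min_reads)
    # prefix sums of sorted qualifying sites per (chrom, context)
    index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for (chrom, context), grp in qual.groupby(["chrom", "context"], sort=False):
        pos0 = grp["pos"].to_numpy() - 1
        order = np.argsort(pos0, kind="stable")
        pos0 = pos0[order]
        fr = grp["site_fraction"].to_numpy()[order]
        index[(chrom, context)] = (pos0, np.concatenate([[0.0], np.cumsum(fr)]))

    rows = []
    has_kind = "kind" in features.columns
    for feat in features.itertuples(index=False):
        for context in CONTEXTS:
            key = (feat.chrom, context)
            if key in index:
                pos0, csum = index[key]
                i0 = int(np.searchsorted(pos0, feat.start, side="left"))
                i1 = int(np.searchsorted(pos0, feat.end, side="left"))
                n = i1 - i0
                frac = (csum[i1] - csum[i0]) / n if n else np.nan
            else:
                n, frac = 0, np.nan
            rows.append(
                {
                    "feature_id": feat.feature_id,
                    "kind": feat.kind if has_kind else "feature",
                    "chrom": feat.chrom,
                    "context": context,
                    "n_qual_sites": n,
                    "fraction": frac,
                    "valid": n >= min_sites,
                }
            )
    out = pd.DataFrame(rows)
    if sample is not None:
        out["sample"] = sample
    return out


def chromosomal_view_windows(
    sites: pd.DataFrame,
    window_size: int = 5000,
    min_sites: int = 10,
    min_reads: int = 10,
    genome: GenomeSpec | None = None,
    sample: str | None = None,
) -> pd.DataFrame:
    """5-kb-view variant of :func:`compute_window_methylation`."""
    crit = WindowCriteria(window_size=window_size, min_sites=min_sites, min_reads=min_reads)
    return compute_window_methylation(sites, crit, genome=genome, sample=sample)
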