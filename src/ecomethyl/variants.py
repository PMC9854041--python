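"""Methylation vs sequence-variation summaries: SNP strata, substitution
z-scores, SV-category methylation, HOT-region coverage accounting."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import IntervalSet

SV_CATEGORIES = ("DEL", "INS", "DUP", "BRK", "INV", "SEQ", "UNCLASSIFIED")

WINDOW_KEY = ["chrom", "start", "end", "context"]


def count_snps_per_window(snps: pd.DataFrame, windows: pd.DataFrame) -> pd.DataFrame:
    """Attach the number of SNP positions falling in each window's span.

    SNP positions are 1-based; window spans are 0-based half-open, so SNP at
    pos p lies in a window iff start < p <= end (equivalently start <= p-1 < end).
    """
    out = windows.copy().reset_index(drop=True)
    out["snp_count"] = 0
    for chrom, grp in out.groupby("chrom", sort=False):
        pos0 = np.sort(snps.loc[snps["chrom"] == chrom, "pos"].to_numpy() - 1)
        if len(pos0) == 0:
            continue
        lo = np.searchsorted(pos0, grp["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos0, grp["end"].to_numpy(), side="left")
        out.loc[grp.index, "snp_count"] = hi - lo
    return out


def snp_window_percentages(windows_with_counts: pd.DataFrame) -> pd.DataFrame:
    """Per context: total windows, with/without SNP counts and percentages."""
    rows = []
    for context, grp in windows_with_counts.groupby("context", sort=True):
        total = len(grp)
        with_snp = int((grp["snp_count"] > 0).sum())
        rows.append(
            {
                "context": context,
                "total_windows": total,
                "windows_with_snp": with_snp,
                "windows_without_snp": total - with_snp,
                "pct_with_snp": round(100.0 * with_snp / total, 1) if total else np.nan,
                "pct_without_snp": round(100.0 * (total - with_snp) / total, 1) if total else np.nan,
            }
        )
    return pd.DataFrame(rows)


def methylation_by_snp_strata(
    windows: pd.DataFrame,
    max_stratum: int = 6,
    group_cols: tuple[str, ...] = ("label", "context"),
) -> pd.DataFrame:
    """Mean/SD of window methylation per SNP-count stratum.

    ``windows`` must carry fraction, snp_count, and the grouping columns
    (region label, context, optionally feature kind). Strata above
    ``max_stratum`` are pooled into the top stratum. Empty strata simply do
    not appear; SD is population SD.
    """
    df = windows.dropna(subset=["fraction"]).copy()
    df["stratum"] = np.minimum(df["snp_count"], max_stratum)
    rows = []
    for key, grp in df.groupby(list(group_cols) + ["stratum"], sort=True):
        vals = grp["fraction"].to_numpy(dtype=float)
        rec = dict(zip(list(group_cols) + ["stratum"], key))
        rec.update(
            n_windows=len(vals),
            mean=float(vals.mean()),
            sd=float(vals.std(ddof=0)),
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def substitution_zscore(
    windows: pd.DataFrame,
    snps: pd.DataFrame,
    group_cols: tuple[str, ...] = ("label", "context"),
) -> pd.DataFrame:
    """Mean z-scored methylation of SNP-containing windows per substitution code.

    z = (x - m) / sigma with m, sigma (population) computed over *all*
    analyzed windows of the same group (region label x context). A window
    holding SNPs of several codes contributes once to each code.
    """
    df = windows.dropna(subset=["fraction"]).copy().reset_index(drop=True)
    rows = []
    for key, grp in df.groupby(list(group_cols), sort=True):
        vals = grp["fraction"].to_numpy(dtype=float)
        m = float(vals.mean())
        sigma = float(vals.std(ddof=0))
        if sigma <= 1e-12:  # identical fractions up to fp noise
            raise ValueError(f"zero methylation variance in group {key}")
        z = (vals - m) / sigma
        zmap = pd.Series(z, index=grp.index)
        # join SNPs into windows of this group
        joined = []
        for chrom, sub in grp.groupby("chrom", sort=False):
            csnps = snps[snps["chrom"] == chrom]
            if csnps.empty:
                continue
            pos0 = csnps["pos"].to_numpy() - 1
            codes = csnps["substitution"].to_numpy()
            order = np.argsort(pos0, kind="stable")
            pos0, codes = pos0[order], codes[order]
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            lo = np.searchsorted(pos0, starts, side="left")
            hi = np.searchsorted(pos0, ends, side="left")
            for widx, (a, b) in zip(sub.index, zip(lo, hi)):
                for code in set(codes[a:b]):
                    joined.append((widx, code))
        if not joined:
            continue
        jdf = pd.DataFrame(joined, columns=["widx", "substitution"]).drop_duplicates()
        jdf["z"] = zmap.loc[jdf["widx"]].to_numpy()
        for code, sub in jdf.groupby("substitution", sort=True):
            rec = dict(zip(list(group_cols), key if isinstance(key, tuple) else (key,)))
            rec.update(
                substitution=code,
                n_windows=len(sub),
                mean_z=float(sub["z"].mean()),
            )
            rows.append(rec)
    return pd.DataFrame(rows)


def sv_methylation_summary(
    svs: pd.DataFrame,
    windows: pd.DataFrame,
    group_cols: tuple[str, ...] = ("sample", "context"),
) -> pd.DataFrame:
    """Mean methylation of valid windows overlapping each SV category.

    ``svs`` has chrom/start/end/category. Windows overlapping SVs of several
    categories count toward each. Categories with no valid windows appear
    with NaN mean and n_windows 0.
    """
    bad = set(svs["category"]) - set(SV_CATEGORIES)
    if bad:
        raise ValueError(f"unknown SV categories: {sorted(bad)}")
    df = windows[windows["valid"]].dropna(subset=["fraction"]).reset_index(drop=True)
    rows = []
    cat_sets = {
        cat: IntervalSet(
            list(zip(sub["chrom"], sub["start"].astype(int), sub["end"].astype(int)))
        ).merge()
        for cat, sub in svs.groupby("category")
    }
    for key, grp in df.groupby(list(group_cols), sort=True):
        keyd = dict(zip(list(group_cols), key if isinstance(key, tuple) else (key,)))
        for cat in SV_CATEGORIES:
            if cat not in cat_sets:
                continue
            flags = pd.Series(False, index=grp.index)
            for chrom, sub in grp.groupby("chrom", sort=False):
                mask = cat_sets[cat].overlaps_point_mask(
                    chrom, sub["start"].to_numpy(), sub["end"].to_numpy()
                )
                flags.loc[sub.index] = mask
            vals = grp.loc[flags, "fraction"].to_numpy(dtype=float)
            rec = dict(keyd)
            rec.update(
                category=cat,
                n_windows=int(flags.sum()),
                mean=float(vals.mean()) if len(vals) else np.nan,
            )
            rows.append(rec)
    return pd.DataFrame(rows)


def hot_coverage(hot: IntervalSet, feature_sets: dict[str, IntervalSet]) -> pd.DataFrame:
    """Base-pair coverage of merged HOT regions by each merged feature set."""
    hot_m = hot.merge()
    total = hot_m.total_bp()
    rows = []
    for name, feats in feature_sets.items():
        covered = hot_m.intersect(feats.merge()).total_bp()
        rows.append(
            {
                "feature": name,
                "covered_bp": covered,
                "hot_bp": total,
                "fraction": covered / total if total else np.nan,
            }
        )
    return pd.DataFrame(rows)
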