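"""Small-RNA profiling, normalization, differential expression, classification.

Differential expression uses a two-group negative-binomial exact test with
tagwise-moderated method-of-moments dispersions and Benjamini-Hochberg
correction. This is a documented stand-in for a quasi-likelihood GLM
workflow; externally computed DE tables can be imported instead via
``read_de_table``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp as _logsumexp

logger = logging.getLogger(__name__)

LENGTH_RANGE = tuple(range(18, 27))
FIVE_PRIME = ("A", "C", "G", "U")

CLASS_COL = "e24sRC_Col"
CLASS_CVI = "e24sRC_Cvi"
CLASS_PARTIAL = "e24sRC_1_2"
CLASS_NONE = "non_e24sRC"
CLASSES = (CLASS_COL, CLASS_CVI, CLASS_PARTIAL, CLASS_NONE)


# ---------------------------------------------------------------------------
# profiling / normalization
# ---------------------------------------------------------------------------

def length_5p_profile(read_classes: pd.DataFrame, total_mapped: int) -> pd.DataFrame:
    """RPM matrix over read length (18-26) x 5'-nucleotide (A/C/G/U).

    ``read_classes`` has columns length, five_prime_nt, count; T is treated
    as U (reads are sequenced as cDNA).
    """
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    df = read_classes.copy()
    df["five_prime_nt"] = df["five_prime_nt"].str.upper().replace({"T": "U"})
    if not df["length"].between(LENGTH_RANGE[0], LENGTH_RANGE[-1]).all():
        raise ValueError("read length outside 18-26")
    if not df["five_prime_nt"].isin(FIVE_PRIME).all():
        raise ValueError("unknown 5' nucleotide")
    out = pd.DataFrame(0.0, index=list(LENGTH_RANGE), columns=list(FIVE_PRIME))
    agg = df.groupby(["length", "five_prime_nt"])["count"].sum()
    for (length, nt), count in agg.items():
        out.loc[length, nt] = count / total_mapped * 1e6
    out.index.name = "length"
    return out


def normalize_counts(
    counts: pd.DataFrame,
    scale: float = 1e6,
    log2: bool = False,
) -> pd.DataFrame:
    """Library-size normalization (CPM for scale=1e6, CP10M for 1e7).

    Library size is the per-sample column sum; optional log2(x+1).
    """
    libsizes = counts.sum(axis=0)
    if (libsizes <= 0).any():
        bad = libsizes.index[libsizes <= 0][0]
        raise ValueError(f"zero library size for sample {bad!r}")
    norm = counts / libsizes * scale
    return np.log2(norm + 1.0) if log2 else norm


def correlate_samples(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of sample columns.

    Zero-variance samples get NaN off-diagonal entries (flagged undefined)
    and 1.0 on the diagonal.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.asarray(corr, dtype=float)
    zero = sd == 0
    corr[zero, :] = np.nan
    corr[:, zero] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=matrix.columns, columns=matrix.columns)


def zscore_standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-score (population SD); constant rows are dropped and logged."""
    x = matrix.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    keep = sd[:, 0] > 0
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("zscore_standardize: dropped %d constant rows", n_drop)
    z = (x[keep] - mu[keep]) / sd[keep]
    return pd.DataFrame(z, index=matrix.index[keep], columns=matrix.columns)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (geometric-mean reference), normalized to
    geometric mean 1; falls back to relative library size when too few
    clusters have full support. Robust to a minority of DE clusters, unlike
    plain CPM scaling."""
    libsizes = counts.sum(axis=0)
    if (libsizes <= 0).any():
        raise ValueError("zero library size")
    full = (counts > 0).all(axis=1)
    if full.sum() >= 10:
        logref = np.log(counts[full]).mean(axis=1, keepdims=True)
        sf = np.exp(np.median(np.log(counts[full]) - logref, axis=0))
    else:
        sf = libsizes / np.exp(np.log(libsizes).mean())
    return sf / np.exp(np.log(sf).mean())


def _moment_dispersions(scaled: np.ndarray, groups: list[np.ndarray], prior_df: float) -> np.ndarray:
    """Tagwise dispersions: pooled within-group MOM estimate shrunk to the median."""
    n_total = sum(len(g) for g in groups)
    df_resid = n_total - len(groups)
    mu = np.zeros(scaled.shape[0])
    ss = np.zeros(scaled.shape[0])
    for g in groups:
        sub = scaled[:, g]
        gm = sub.mean(axis=1)
        ss += ((sub - gm[:, None]) ** 2).sum(axis=1)
        mu += gm * len(g)
    mu /= n_total
    var = ss / max(df_resid, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (var - mu) / mu**2
    raw = np.where(np.isfinite(raw), raw, 0.0)
    raw = np.clip(raw, 1e-8, 10.0)
    common = float(np.median(raw))
    if df_resid <= 0:
        return np.full(scaled.shape[0], common)
    w = df_resid / (df_resid + prior_df)
    return w * raw + (1 - w) * common


def _exact_nb_pvalue(s_a: int, s_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Exact conditional two-sided p for group sums under a shared NB mean.

    Group sums of i.i.d. NB(mu, phi) counts are NB with mean n_g*mu and
    dispersion phi/n_g. Conditional on the total, probabilities at every
    split are computed and all splits no more probable than the observed one
    are summed (edgeR-style two-sided exact test).
    """
    total = s_a + s_b
    if total == 0:
        return 1.0
    mu = total / (n_a + n_b)
    if total > 500_000:
        # normal approximation for very deep clusters (keeps memory bounded)
        mu_a = n_a * mu
        var_a = mu_a + (phi / n_a) * mu_a**2
        z = (s_a - mu_a) / np.sqrt(max(var_a, 1e-12))
        return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    k = np.arange(total + 1)
    if phi < 1e-6:
        # Poisson limit: conditional distribution is binomial
        logp = stats.binom.logpmf(k, total, n_a / (n_a + n_b))
    else:
        r_a, r_b = n_a / phi, n_b / phi
        mu_a, mu_b = n_a * mu, n_b * mu
        p_a, p_b = r_a / (r_a + mu_a), r_b / (r_b + mu_b)
        logp = stats.nbinom.logpmf(k, r_a, p_a) + stats.nbinom.logpmf(k[::-1], r_b, p_b)
        logp = logp - _logsumexp(logp)
    obs = logp[s_a]
    p = float(np.exp(_logsumexp(logp[logp <= obs + 1e-10]) - _logsumexp(logp)))
    return min(p, 1.0)


def test_differential_expression(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    prior_df: float = 10.0,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Two-group NB exact test per cluster with BH correction.

    Returns a frame indexed by cluster id with mean_a, mean_b, log2fc
    (group_a over group_b), pvalue, fdr. All-zero clusters are excluded and
    logged. With fewer than 2 replicates in either group a Poisson
    (binomial-conditional) fallback is used.
    """
    for s in group_a + group_b:
        if s not in counts.columns:
            raise ValueError(f"sample {s!r} not in count matrix")
    sub = counts[group_a + group_b]
    nonzero = sub.sum(axis=1) > 0
    n_drop = int((~nonzero).sum())
    if n_drop:
        logger.info("test_differential_expression: excluded %d all-zero clusters", n_drop)
    sub = sub.loc[nonzero]
    sf = _size_factors(sub.to_numpy(dtype=float))
    scaled = sub.to_numpy(dtype=float) / sf[None, :]

    n_a, n_b = len(group_a), len(group_b)
    ia = np.arange(n_a)
    ib = np.arange(n_a, n_a + n_b)
    poisson = n_a < 2 or n_b < 2
    if poisson:
        phis = np.zeros(scaled.shape[0])
    else:
        phis = _moment_dispersions(scaled, [ia, ib], prior_df)

    s_a = np.rint(scaled[:, ia].sum(axis=1)).astype(np.int64)
    s_b = np.rint(scaled[:, ib].sum(axis=1)).astype(np.int64)
    pvals = np.array(
        [
            _exact_nb_pvalue(int(a), int(b), n_a, n_b, float(phi))
            for a, b, phi in zip(s_a, s_b, phis)
        ]
    )
    mean_a = scaled[:, ia].mean(axis=1)
    mean_b = scaled[:, ib].mean(axis=1)
    log2fc = np.log2((mean_a + prior_count) / (mean_b + prior_count))
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": bh_adjust(pvals),
        },
        index=sub.index,
    )


# not a pytest test, despite the conventional DE-analysis name
test_differential_expression.__test__ = False  # type: ignore[attr-defined]


def read_de_table(path) -> pd.DataFrame:
    """Import an externally computed DE table (cluster_id, log2fc, pvalue, fdr)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    required = {"log2fc", "pvalue", "fdr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_e24src(
    stage_results: dict[str, pd.DataFrame],
    fdr: float = 0.05,
    fc: float = 2.0,
    stages: tuple[str, ...] = ("FH", "AR", "GS"),
) -> pd.DataFrame:
    """Classify clusters from per-stage Col-vs-Cvi DE results.

    Significant in all three stages with Col higher everywhere -> e24sRC_Col;
    Cvi higher everywhere -> e24sRC_Cvi; significant in 1-2 stages (or all 3
    with mixed direction) -> e24sRC_1_2; never significant -> non_e24sRC.
    log2fc in the inputs is Col over Cvi.
    """
    missing = [s for s in stages if s not in stage_results]
    if missing:
        raise ValueError(f"missing stage DE results: {missing}")
    lfc_thresh = np.log2(fc)
    ids = stage_results[stages[0]].index
    for s in stages[1:]:
        ids = ids.intersection(stage_results[s].index)
    sig = pd.DataFrame(index=ids)
    up = pd.DataFrame(index=ids)
    for s in stages:
        r = stage_results[s].loc[ids]
        sig[s] = (r["fdr"] < fdr) & (r["log2fc"].abs() >= lfc_thresh)
        up[s] = r["log2fc"] > 0
    n_sig = sig.sum(axis=1)
    all_up = up.all(axis=1)
    all_down = (~up).all(axis=1)
    cls = np.full(len(ids), CLASS_NONE, dtype=object)
    cls[(n_sig > 0)] = CLASS_PARTIAL
    cls[(n_sig == len(stages)) & all_up] = CLASS_COL
    cls[(n_sig == len(stages)) & all_down] = CLASS_CVI
    out = pd.DataFrame({"n_significant_stages": n_sig, "class": cls}, index=ids)
    for s in stages:
        out[f"log2fc_{s}"] = stage_results[s].loc[ids, "log2fc"]
        out[f"fdr_{s}"] = stage_results[s].loc[ids, "fdr"]
    return out
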