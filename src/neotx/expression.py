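"""Normalization and per-gene two-group differential expression.

The differential-expression stage is a fully specified negative-binomial
Wald test on normalized counts: median-of-ratios size factors, per-gene
method-of-moments dispersions shrunk toward the trimmed-mean dispersion,
a delta-method standard error for the log2 fold change, and Benjamini-
Hochberg FDR control.  It deliberately omits fold-change shrinkage, Cook's
outlier filtering and independent filtering, so every number it produces is
reproducible from the formulas documented here.

TMM (trimmed mean of M-values) factors are provided for reporting
normalized per-sample expression; the implementation mirrors the standard
edgeR computation (doubly trimmed, precision-weighted mean of log ratios
against a reference column chosen by upper-quartile proximity).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "size_factors_median_of_ratios",
    "tmm_factors",
    "estimate_dispersion",
    "nb_wald_test",
    "bh_adjust",
    "log_normalized_matrix",
]


def _as_float_matrix(counts: pd.DataFrame) -> np.ndarray:
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return arr


def _rescale_geomean(factors: np.ndarray) -> np.ndarray:
    return factors / np.exp(np.mean(np.log(factors)))


def size_factors_median_of_ratios(
    counts: pd.DataFrame, pseudo_reference: bool = False
) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Per sample: the median over genes of count / geometric-mean-across-
    samples, using only genes with all-positive counts.  If no gene is
    positive in every sample, the default raises; ``pseudo_reference=True``
    switches the per-gene reference to the geometric mean over the samples
    in which the gene is observed, so genes positive in most samples still
    anchor the ratios.
    """
    arr = _as_float_matrix(counts)
    all_pos = (arr > 0).all(axis=1)
    if all_pos.any() and not pseudo_reference:
        sub = arr[all_pos]
        ref = np.exp(np.mean(np.log(sub), axis=1))
        factors = np.median(sub / ref[:, None], axis=0)
    elif pseudo_reference:
        pos = arr > 0
        n_pos = pos.sum(axis=1)
        usable = n_pos > 0
        if not usable.any():
            raise ValueError("count matrix has no positive entries")
        with np.errstate(divide="ignore"):
            logs = np.where(pos, np.log(np.where(pos, arr, 1.0)), 0.0)
        ref = np.exp(logs[usable].sum(axis=1) / n_pos[usable])
        ratios = np.where(
            pos[usable], arr[usable] / ref[:, None], np.nan
        )
        factors = np.nanmedian(ratios, axis=0)
    else:
        raise ValueError(
            "no gene has positive counts in every sample; "
            "retry with pseudo_reference=True"
        )
    if (factors <= 0).any() or not np.isfinite(factors).all():
        raise ValueError("degenerate size factors; check the count matrix")
    return pd.Series(_rescale_geomean(factors), index=counts.columns, name="size_factor")


def tmm_factors(
    counts: pd.DataFrame,
    trim_logratio: float = 0.30,
    trim_abs: float = 0.05,
    ref_column: str | None = None,
    combine_library_size: bool = True,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    For each sample against the reference column, M (log2 ratio of library-
    scaled proportions) and A (average log2 proportion) are computed over
    genes positive in both; the upper and lower ``trim_logratio`` tails of M
    and ``trim_abs`` tails of A are discarded; the composition factor is two
    to the precision-weighted mean of the surviving M values.  The reference
    is the column whose upper-quartile of scaled counts is closest to the
    mean upper-quartile.

    By default the returned factor is the full normalization divisor,
    library size times composition factor (so a sample scaled up 4x gets a
    4x larger factor); ``combine_library_size=False`` returns the bare
    composition factors as edgeR reports them.  Either way the factors are
    rescaled to geometric mean 1.
    """
    arr = _as_float_matrix(counts)
    libsize = arr.sum(axis=0)
    if (libsize == 0).any():
        raise ValueError("every sample must have a positive library size")
    scaled = arr / libsize
    if ref_column is None:
        uq = np.array([np.quantile(scaled[:, j][arr[:, j] > 0], 0.75)
                       for j in range(arr.shape[1])])
        ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_j = int(counts.columns.get_loc(ref_column))

    factors = np.ones(arr.shape[1])
    ref = arr[:, ref_j]
    n_ref = libsize[ref_j]
    for j in range(arr.shape[1]):
        obs = arr[:, j]
        n_obs = libsize[j]
        keep = (obs > 0) & (ref > 0)
        if not keep.any():
            raise ValueError(f"no gene positive in both sample {j} and reference")
        o, r = obs[keep], ref[keep]
        m = np.log2((o / n_obs) / (r / n_ref))
        a = 0.5 * (np.log2(o / n_obs) + np.log2(r / n_ref))
        # asymptotic (delta-method) variance of M under binomial sampling
        v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
        if np.max(np.abs(m)) < 1e-6:
            continue
        n = m.size
        lo_l = np.floor(n * trim_logratio) + 1
        hi_l = n + 1 - lo_l
        lo_s = np.floor(n * trim_abs) + 1
        hi_s = n + 1 - lo_s
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        sel = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
        if not sel.any():
            continue
        factors[j] = 2.0 ** (np.sum(m[sel] / v[sel]) / np.sum(1.0 / v[sel]))
    if combine_library_size:
        factors = factors * libsize
    return pd.Series(_rescale_geomean(factors), index=counts.columns, name="tmm_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    groups: pd.Series | dict[str, list[str]],
    size_factors: pd.Series | None = None,
    shrink_weight: float = 0.5,
    trim: float = 0.1,
    floor: float = 1e-8,
) -> pd.Series:
    """Per-gene NB dispersion by method of moments with trimmed-mean shrinkage.

    Normalized counts are pooled within groups: the within-group variance
    (pooled over groups) and the overall mean give the raw estimate
    ``max(0, (s2 - m) / m**2)``, which is then averaged 50/50 with the
    trimmed mean of raw estimates across genes and floored.

    ``groups`` maps sample id -> group label (Series) or group label ->
    sample ids (dict); every group needs at least two samples.
    """
    if size_factors is None:
        size_factors = size_factors_median_of_ratios(counts)
    norm = counts.to_numpy(dtype=float) / size_factors.reindex(counts.columns).to_numpy()

    if isinstance(groups, pd.Series):
        group_map: dict[str, list[str]] = {}
        for sid, g in groups.items():
            group_map.setdefault(g, []).append(sid)
    else:
        group_map = {g: list(v) for g, v in groups.items()}

    col_idx = {c: i for i, c in enumerate(counts.columns)}
    ss = np.zeros(counts.shape[0])
    df = 0
    n_total = 0
    total = np.zeros(counts.shape[0])
    for g, sids in group_map.items():
        idx = [col_idx[s] for s in sids]
        if len(idx) < 2:
            raise ValueError(f"group {g!r} needs at least two samples")
        sub = norm[:, idx]
        ss += sub.var(axis=1, ddof=1) * (len(idx) - 1)
        df += len(idx) - 1
        total += sub.sum(axis=1)
        n_total += len(idx)
    s2 = ss / df
    mean = total / n_total
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mean > 0, np.maximum(0.0, (s2 - mean) / mean**2), 0.0)
    prior = stats.trim_mean(raw[mean > 0], trim) if (mean > 0).any() else 0.0
    shrunk = np.maximum(floor, (1 - shrink_weight) * raw + shrink_weight * prior)
    return pd.Series(shrunk, index=counts.index, name="dispersion")


def nb_wald_test(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    size_factors: pd.Series,
    dispersions: pd.Series,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene Wald test of group B vs reference group A on NB counts.

    The log2 fold change is ``log2((mean_B + pc) / (mean_A + pc))`` on
    size-factor-normalized counts.  Its standard error comes from the NB
    delta method: a normalized count with true level q has variance
    ``q / s + alpha * q**2``, so the variance of a group mean is
    ``q * sum(1/s_i) / n**2 + alpha * q**2 / n``, plugged in at the observed
    group means.  Genes with zero counts in every sample of both groups get
    NaN p-values and are excluded from the FDR denominator.
    """
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    sf = size_factors.reindex(counts.columns)
    norm = counts.to_numpy(dtype=float) / sf.to_numpy()
    col_idx = {c: i for i, c in enumerate(counts.columns)}
    ia = [col_idx[s] for s in group_a]
    ib = [col_idx[s] for s in group_b]
    alpha = dispersions.reindex(counts.index).to_numpy(dtype=float)

    sub_a, sub_b = norm[:, ia], norm[:, ib]
    mean_a = sub_a.mean(axis=1) + pseudocount
    mean_b = sub_b.mean(axis=1) + pseudocount
    log2fc = np.log2(mean_b / mean_a)

    inv_a = sum(1.0 / sf.iloc[i] for i in ia)
    inv_b = sum(1.0 / sf.iloc[i] for i in ib)
    na, nb = len(ia), len(ib)
    var_mean_a = mean_a * inv_a / na**2 + alpha * mean_a**2 / na
    var_mean_b = mean_b * inv_b / nb**2 + alpha * mean_b**2 / nb
    ln2sq = np.log(2.0) ** 2
    se = np.sqrt((var_mean_a / mean_a**2 + var_mean_b / mean_b**2) / ln2sq)

    wald = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(wald))
    all_zero = (counts.to_numpy()[:, ia + ib] == 0).all(axis=1)
    p = np.where(all_zero, np.nan, p)

    res = pd.DataFrame(
        {
            "base_mean": norm[:, ia + ib].mean(axis=1),
            "log2fc": log2fc,
            "se": se,
            "wald_stat": wald,
            "p": p,
            "padj": bh_adjust(pd.Series(p, index=counts.index)).to_numpy(),
        },
        index=counts.index,
    )
    return res


def bh_adjust(pvalues: pd.Series | np.ndarray | list) -> pd.Series:
    """Benjamini-Hochberg step-up adjustment; NaN entries pass through.

    The denominator is the number of defined p-values only.
    """
    s = pd.Series(pvalues, dtype=float)
    defined = s.notna()
    vals = s[defined].to_numpy()
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = pd.Series(np.nan, index=s.index)
    if defined.any():
        out[defined] = multipletests(vals, method="fdr_bh")[1]
    return out


def log_normalized_matrix(
    counts: pd.DataFrame, size_factors: pd.Series, pseudocount: float = 1.0
) -> pd.DataFrame:
    """log2(count / size_factor + pseudocount), same shape as counts."""
    sf = size_factors.reindex(counts.columns)
    if (sf <= 0).any():
        raise ValueError("size factors must be positive")
    return np.log2(counts / sf + pseudocount)
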