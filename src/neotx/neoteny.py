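"""Concordant differential expression and neoteny classification.

This module houses the comparative core of the pipeline.  Genes significant
(adjusted p < alpha) in both parasite-vs-adult contrasts with matching fold-
change sign form the concordantly differentially expressed (CDE) set.  Each
gene is then labelled juvenile-like (neotenic) when its parasite-vs-adult
direction matches its juvenile-vs-adult direction in the non-parasitic
species, or adult-like when the directions oppose; a chi-squared test of
independence asks whether juvenile-like labels are enriched in the DE set
relative to the background.  PCA of log-normalized expression with one-way
ANOVA on component scores, and the relaxed-threshold candidate-gene report,
complete the stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "JUVENILE_LIKE",
    "ADULT_LIKE",
    "UNDEFINED",
    "NeotenyTestResult",
    "PCAResult",
    "AnovaResult",
    "significant_set",
    "concordant_de",
    "classify_neoteny",
    "classify_neoteny_table",
    "neoteny_fraction",
    "neoteny_enrichment_test",
    "pca_expression",
    "anova_pc_scores",
    "candidate_gene_report",
]

JUVENILE_LIKE = "juvenile_like"
ADULT_LIKE = "adult_like"
UNDEFINED = "undefined"


@dataclass(frozen=True)
class NeotenyTestResult:
    """2x2 independence test of juvenile-like labels, DE set vs background.

    ``table`` rows are (DE set, background), columns (juvenile_like,
    adult_like).  Percentages are of defined labels within each row.
    """

    table: np.ndarray
    chi2: float
    df: int
    p: float
    percent_de_neotenic: float
    percent_background_neotenic: float


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame  # samples x components
    variance_fraction: np.ndarray


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


def significant_set(contrast: pd.DataFrame, alpha: float = 0.05) -> set[str]:
    """Gene ids with defined adjusted p strictly below ``alpha``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    padj = contrast["padj"]
    return set(contrast.index[padj.notna() & (padj < alpha)])


def concordant_de(
    contrast_p1: pd.DataFrame,
    contrast_p2: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Concordantly DE genes: significant in both contrasts, same lfc sign.

    Both contrasts must be computed against the same reference group (the
    adult non-parasite) over the same gene universe.  Returns the CDE table
    (gene_id, sign, per-contrast lfc and padj) and the discordant table
    (significant in both, opposite signs), each sorted by gene id.
    """
    if not contrast_p1.index.equals(contrast_p2.index):
        raise ValueError("contrasts cover different gene universes")
    sig = sorted(significant_set(contrast_p1, alpha) & significant_set(contrast_p2, alpha))
    s1 = np.sign(contrast_p1.loc[sig, "log2fc"]).astype(int)
    s2 = np.sign(contrast_p2.loc[sig, "log2fc"]).astype(int)
    both = pd.DataFrame(
        {
            "sign": s1.where(s1 == s2, 0),
            "lfc_p1": contrast_p1.loc[sig, "log2fc"],
            "lfc_p2": contrast_p2.loc[sig, "log2fc"],
            "padj_p1": contrast_p1.loc[sig, "padj"],
            "padj_p2": contrast_p2.loc[sig, "padj"],
        },
        index=pd.Index(sig, name="gene_id"),
    )
    concordant = (s1 == s2) & (s1 != 0)
    return both[concordant], both[~concordant]


def classify_neoteny(lfc_parasite_vs_adult: float, lfc_juvenile_vs_adult: float) -> str:
    """Label a gene from the signs of its parasite and juvenile contrasts.

    Same nonzero sign -> juvenile_like; opposite nonzero signs -> adult_like;
    an exactly zero fold change in either contrast -> undefined.
    """
    s_p = np.sign(lfc_parasite_vs_adult)
    s_j = np.sign(lfc_juvenile_vs_adult)
    if s_p == 0 or s_j == 0:
        return UNDEFINED
    return JUVENILE_LIKE if s_p == s_j else ADULT_LIKE


def classify_neoteny_table(
    lfc_parasite: pd.Series, lfc_juvenile: pd.Series
) -> pd.Series:
    """Vectorized :func:`classify_neoteny` over a shared gene index."""
    s_p = np.sign(lfc_parasite.to_numpy())
    s_j = np.sign(lfc_juvenile.reindex(lfc_parasite.index).to_numpy())
    out = np.where(
        (s_p == 0) | (s_j == 0),
        UNDEFINED,
        np.where(s_p == s_j, JUVENILE_LIKE, ADULT_LIKE),
    )
    return pd.Series(out, index=lfc_parasite.index, name="neoteny_label")


def neoteny_fraction(labels) -> float:
    """Percent of defined labels that are juvenile-like."""
    arr = pd.Series(list(labels))
    n_juv = int((arr == JUVENILE_LIKE).sum())
    n_adu = int((arr == ADULT_LIKE).sum())
    if n_juv + n_adu == 0:
        raise ValueError("no defined labels")
    return 100.0 * n_juv / (n_juv + n_adu)


def neoteny_enrichment_test(
    de_labels, background_labels, yates: bool = False
) -> NeotenyTestResult:
    """Chi-squared test of independence of label vs DE membership.

    ``background_labels`` should normally be the complement of the DE set
    (disjoint rows); the caller may pass all genes to reproduce a marginal
    comparison.  Undefined labels are excluded.  Expected cell counts of
    zero raise, naming the offending cell.
    """
    de = pd.Series(list(de_labels))
    bg = pd.Series(list(background_labels))
    table = np.array(
        [
            [(de == JUVENILE_LIKE).sum(), (de == ADULT_LIKE).sum()],
            [(bg == JUVENILE_LIKE).sum(), (bg == ADULT_LIKE).sum()],
        ],
        dtype=int,
    )
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        row_sums, col_sums = table.sum(axis=1), table.sum(axis=0)
        expected = np.outer(row_sums, col_sums) / max(table.sum(), 1)
        i, j = np.unravel_index(np.argmin(expected), expected.shape)
        rows = ("de", "background")
        cols = (JUVENILE_LIKE, ADULT_LIKE)
        raise ValueError(
            f"expected count is zero in cell ({rows[i]}, {cols[j]}); "
            "the test is undefined"
        )
    chi2, p, df, _ = stats.chi2_contingency(table, correction=yates)
    return NeotenyTestResult(
        table=table,
        chi2=float(chi2),
        df=int(df),
        p=float(p),
        percent_de_neotenic=100.0 * table[0, 0] / table[0].sum(),
        percent_background_neotenic=100.0 * table[1, 0] / table[1].sum(),
    )


def pca_expression(
    logmatrix: pd.DataFrame,
    n_components: int | None = None,
    center: bool = True,
    scale: bool = False,
) -> PCAResult:
    """PCA of a log-normalized genes x samples matrix.

    Samples are observations and genes variables; genes are centered (and
    optionally scaled to unit variance).  For determinism each component's
    sign is fixed so its largest-magnitude gene loading is positive.
    """
    x = logmatrix.to_numpy(dtype=float).T  # samples x genes
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least two samples")
    if np.allclose(x.var(axis=0), 0):
        raise ValueError("expression matrix is constant across samples")
    if center:
        x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=0)
        x = x / np.where(sd > 0, sd, 1.0)
    k = n_components or min(x.shape)
    pca = PCA(n_components=min(k, min(x.shape)), svd_solver="full")
    scores = pca.fit_transform(x)
    # sign convention: largest-|loading| positive per component
    for c in range(scores.shape[1]):
        load = pca.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, c] *= -1.0
    scores_df = pd.DataFrame(
        scores,
        index=logmatrix.columns,
        columns=[f"PC{c + 1}" for c in range(scores.shape[1])],
    )
    return PCAResult(scores=scores_df, variance_fraction=pca.explained_variance_ratio_)


def anova_pc_scores(scores: pd.Series, groups: pd.Series) -> AnovaResult:
    """One-way fixed-effects ANOVA of per-sample scores across groups."""
    groups = groups.reindex(scores.index)
    if groups.isna().any():
        missing = list(scores.index[groups.isna()])
        raise ValueError(f"samples missing a group label: {missing}")
    arrays = [scores[groups == g].to_numpy() for g in groups.unique()]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(len(a) < 1 for a in arrays):
        raise ValueError("every group needs at least one sample")
    f_stat, p = stats.f_oneway(*arrays)
    df_between = len(arrays) - 1
    df_within = sum(len(a) for a in arrays) - len(arrays)
    return AnovaResult(F=float(f_stat), df_between=df_between, df_within=df_within, p=float(p))


def candidate_gene_report(
    contrasts: dict[str, pd.DataFrame],
    candidates: list[str],
    alpha: float = 0.1,
    tmm_matrix: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """A-priori candidate genes at a relaxed FDR threshold.

    For each candidate gene and each named contrast: log2 fold change,
    adjusted p, a pass flag (padj < alpha, strict) and a +/- direction
    symbol.  TMM-normalized per-sample values are attached for plotting when
    ``tmm_matrix`` is given.  Candidates absent from the gene universe are
    returned separately, not fatal.
    """
    rows = []
    missing = []
    for gene in candidates:
        present = all(gene in c.index for c in contrasts.values())
        if not present:
            missing.append(gene)
            continue
        for name, contrast in contrasts.items():
            lfc = float(contrast.loc[gene, "log2fc"])
            padj = contrast.loc[gene, "padj"]
            rows.append(
                {
                    "gene_id": gene,
                    "contrast": name,
                    "log2fc": lfc,
                    "padj": padj,
                    "pass": bool(pd.notna(padj) and padj < alpha),
                    "direction": "+" if lfc > 0 else ("-" if lfc < 0 else "0"),
                }
            )
    report = pd.DataFrame(
        rows, columns=["gene_id", "contrast", "log2fc", "padj", "pass", "direction"]
    )
    if tmm_matrix is not None and not report.empty:
        values = tmm_matrix.reindex(report["gene_id"].unique())
        report = report.merge(
            values.rename_axis("gene_id").reset_index(), on="gene_id", how="left"
        )
    return report, missing
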