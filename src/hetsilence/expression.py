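"""Distribution-shift and correlation statistics on per-gene expression
change tables.

Tables carry one log2 fold-change column per genotype contrast and a
gene category (mobile genetic element vs. all other genes).  The upstream
differential-expression estimation is out of scope; tables are inputs.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

GENE_CATEGORIES = ("MGE", "other")

__all__ = ["GENE_CATEGORIES", "validate_gene_table", "mge_shift_test", "genotype_spearman"]


def validate_gene_table(table: pd.DataFrame) -> pd.DataFrame:
    if "gene_id" not in table.columns or "category" not in table.columns:
        raise ValueError("gene table needs 'gene_id' and 'category' columns")
    if table["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id entries")
    bad = set(table["category"]) - set(GENE_CATEGORIES)
    if bad:
        raise ValueError(f"unknown gene categories: {sorted(bad)}")
    return table


def mge_shift_test(table: pd.DataFrame, contrast: str) -> tuple[float, float]:
    """Mann-Whitney U comparing MGE vs other gene log2FC distributions.

    Returns ``(U, two-sided P)`` with U for the MGE sample.  The exact
    null distribution is used for small samples without ties, the normal
    approximation with tie correction otherwise (scipy's automatic rule).
    """
    validate_gene_table(table)
    x = table.loc[table["category"] == "MGE", contrast].dropna().to_numpy()
    y = table.loc[table["category"] == "other", contrast].dropna().to_numpy()
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 genes per category")
    if np.array_equal(np.sort(x), np.sort(y)) and np.unique(x).size == 1:
        return float(x.size * y.size / 2.0), 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def genotype_spearman(
    table: pd.DataFrame, category: str, contrasts: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlation of log2FC columns within one category.

    Returns ``(rho, pvals)`` as symmetric DataFrames with unit diagonal.
    A constant column yields NaN correlations (flagged missing) rather
    than an error.
    """
    validate_gene_table(table)
    if category not in GENE_CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    sub = table.loc[table["category"] == category, contrasts].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 genes in category")
    k = len(contrasts)
    rho = np.eye(k)
    pv = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            xi = sub[contrasts[i]].to_numpy()
            xj = sub[contrasts[j]].to_numpy()
            if np.unique(xi).size == 1 or np.unique(xj).size == 1:
                r, p = np.nan, np.nan
            else:
                r, p = stats.spearmanr(xi, xj)
            rho[i, j] = rho[j, i] = r
            pv[i, j] = pv[j, i] = p
    idx = pd.Index(contrasts)
    return (
        pd.DataFrame(rho, index=idx, columns=idx),
        pd.DataFrame(pv, index=idx, columns=idx),
    )


def density_plot(table: pd.DataFrame, contrast: str, ax=None):
    """Optional helper: MGE vs other log2FC density plot (untested surface)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for cat, color in (("other", "0.6"), ("MGE", "purple")):
        vals = table.loc[table["category"] == cat, contrast].dropna()
        vals.plot.kde(ax=ax, label=cat, color=color)
    ax.set_xlabel(f"log2 fold change ({contrast})")
    ax.legend()
    return ax
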