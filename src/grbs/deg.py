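"""DEG calling at fold-change/p/FDR cutoffs and WT-vs-knockdown categories.

A gene is differentially expressed when |fold change| > 1.5 (that is,
|log2FC| > log2 1.5), p < 0.01 and FDR < 0.05, all strict.  Comparing the
wild-type and BRG1-knockdown contrasts yields four categories: ``common``
(DEG in both), ``lost`` (wild-type only), ``gained`` (knockdown only) and
``neither``.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .signal import rank_sum_test

DEG_CATEGORIES = ("common", "lost", "gained", "neither")

DEFAULT_FC = 1.5
DEFAULT_P = 0.01
DEFAULT_FDR = 0.05


def call_degs(
    table: pd.DataFrame,
    fc_threshold: float = DEFAULT_FC,
    p_threshold: float = DEFAULT_P,
    fdr_threshold: float = DEFAULT_FDR,
) -> pd.Series:
    """Boolean DEG call per row (indexed by gene_id).

    Strict inequalities throughout; the fold-change cutoff applies to the
    absolute fold change, so down-regulated genes qualify symmetrically.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must exceed 1")
    if p_threshold <= 0 or fdr_threshold <= 0:
        raise ValueError("thresholds must be positive")
    lfc_cut = math.log2(fc_threshold)
    calls = (
        (table["log2fc"].abs() > lfc_cut)
        & (table["pvalue"] < p_threshold)
        & (table["fdr"] < fdr_threshold)
    )
    calls.index = pd.Index(table["gene_id"], name="gene_id")
    return calls


def categorize(wt_calls: pd.Series, kd_calls: pd.Series) -> pd.DataFrame:
    """Per-gene category from the two contrasts' DEG calls.

    Gene universes are outer-joined; a gene absent from one table counts
    as not-DEG there (with a warning).  Duplicate gene ids within either
    input are a hard error.
    """
    for name, calls in (("wild-type", wt_calls), ("knockdown", kd_calls)):
        if calls.index.has_duplicates:
            dup = calls.index[calls.index.duplicated()][0]
            raise ValueError(f"duplicate gene_id {dup!r} in {name} table")
    universe = wt_calls.index.union(kd_calls.index)
    n_missing = (len(universe) - len(wt_calls)) + (len(universe) - len(kd_calls))
    if n_missing:
        warnings.warn(
            f"{n_missing} gene(s) absent from one contrast treated as not-DEG there",
            stacklevel=2,
        )
    wt = wt_calls.reindex(universe, fill_value=False).astype(bool)
    kd = kd_calls.reindex(universe, fill_value=False).astype(bool)
    category = np.select(
        [wt & kd, wt & ~kd, ~wt & kd], ["common", "lost", "gained"], default="neither"
    )
    return pd.DataFrame(
        {"gene_id": universe, "status_wt": wt.to_numpy(), "status_kd": kd.to_numpy(),
         "category": category}
    ).reset_index(drop=True)


def absolute_fc_comparison(
    categories: pd.DataFrame, wt_table: pd.DataFrame, kd_table: pd.DataFrame
) -> pd.DataFrame:
    """Per category, |log2FC| in wild-type vs knockdown with rank-sum p.

    Empty categories are omitted with a warning.
    """
    wt_lfc = wt_table.set_index("gene_id")["log2fc"].abs()
    kd_lfc = kd_table.set_index("gene_id")["log2fc"].abs()
    rows = []
    for cat in DEG_CATEGORIES[:3]:
        genes = categories.loc[categories["category"] == cat, "gene_id"]
        a = wt_lfc.reindex(genes).dropna().to_numpy()
        b = kd_lfc.reindex(genes).dropna().to_numpy()
        if a.size == 0 or b.size == 0:
            warnings.warn(f"category {cat!r} empty; row omitted", stacklevel=2)
            continue
        res = rank_sum_test(a, b)
        rows.append(
            {"category": cat, "n": int(len(genes)),
             "median_abs_log2fc_wt": float(np.median(a)),
             "median_abs_log2fc_kd": float(np.median(b)),
             "p_value": res.p_value, "method": res.method}
        )
    return pd.DataFrame(rows)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order.

    q_(i) = min_{j >= i} p_(j) * n / j over the ascending order statistics,
    capped at 1.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
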