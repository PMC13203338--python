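"""Two-group validation of hub genes with an assumption-gated test.

For each gene, expression in the high- and low-feed-efficiency groups is
compared with an independent-samples t-test when both groups pass the
Shapiro-Wilk normality test and Levene's variance-homogeneity test at the
gate level (default alpha = 0.05); otherwise the Mann-Whitney U test is
used.  Fold changes are log2(mean_low / mean_high) on arithmetic group
means, p-values are Benjamini-Hochberg adjusted within the tested panel,
and q < 0.1 flags significance.  Validated genes are then correlated with
average daily gain to separate efficiency-specific genes from general
growth genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .module_trait import pearson_with_pvalue

__all__ = [
    "GroupComparison",
    "choose_test",
    "two_group_compare",
    "bh_adjust",
    "correlate_with_adg",
]


@dataclass
class GroupComparison:
    gene_id: str
    mean_high: float
    mean_low: float
    log2fc: float  # low relative to high; negative = higher in high-efficiency
    test_used: str  # "t" or "mann_whitney"
    p: float
    q: float
    significant: bool


def choose_test(x, y, alpha_gate: float = 0.05) -> str:
    """Pick "t" or "mann_whitney" from the normality/variance gates.

    "t" requires Shapiro-Wilk p > alpha_gate in BOTH groups and
    mean-centred Levene p > alpha_gate; anything else falls back to the
    rank test.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each group needs at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return "mann_whitney"  # Shapiro undefined on constant data
    sw_x = stats.shapiro(x).pvalue
    sw_y = stats.shapiro(y).pvalue
    lev = stats.levene(x, y, center="mean").pvalue
    if sw_x > alpha_gate and sw_y > alpha_gate and lev > alpha_gate:
        return "t"
    return "mann_whitney"


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order, capped at 1.
    """
    p = np.asarray(p_values, float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D array")
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, None, 1.0)
    return q


def two_group_compare(
    expr_high: pd.DataFrame,
    expr_low: pd.DataFrame,
    genes: list[str] | None = None,
    alpha_gate: float = 0.05,
    q_threshold: float = 0.1,
) -> pd.DataFrame:
    """Gated per-gene comparison of two cohorts (genes x samples frames).

    Returns one row per gene with the test used, two-sided p, BH q over
    the tested panel, log2 fold change of low relative to high, and the
    q < ``q_threshold`` significance flag.  Genes with a non-positive
    group mean get log2fc = NaN but are still tested.
    """
    if genes is None:
        genes = expr_high.index.tolist()
    missing_h = set(genes) - set(expr_high.index)
    missing_l = set(genes) - set(expr_low.index)
    if missing_h or missing_l:
        raise ValueError(
            f"genes absent from cohorts: high={sorted(missing_h)[:5]}, "
            f"low={sorted(missing_l)[:5]}"
        )
    rows = []
    for g in genes:
        x = expr_high.loc[g].to_numpy(float)  # high-efficiency group
        y = expr_low.loc[g].to_numpy(float)
        test = choose_test(x, y, alpha_gate)
        if test == "t":
            p = float(stats.ttest_ind(x, y, equal_var=True).pvalue)
        else:
            p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        mh, ml = float(x.mean()), float(y.mean())
        log2fc = float(np.log2(ml / mh)) if mh > 0 and ml > 0 else float("nan")
        rows.append((g, mh, ml, log2fc, test, p))
    out = pd.DataFrame(
        rows, columns=["gene_id", "mean_high", "mean_low", "log2fc", "test_used", "p"]
    )
    out["q"] = bh_adjust(np.clip(out["p"].to_numpy(), np.nextafter(0, 1), 1.0))
    out["significant"] = out["q"] < q_threshold
    return out


def correlate_with_adg(
    expr: pd.DataFrame, adg: pd.Series, p_threshold: float = 0.05
) -> pd.DataFrame:
    """Per-gene Pearson correlation of expression with average daily gain.

    ``expr`` is genes x individuals; ``adg`` is indexed by individual.
    Genes with p < ``p_threshold`` are flagged growth-correlated.
    """
    missing = expr.columns.difference(adg.index)
    if len(missing):
        raise ValueError(f"ADG missing for individuals: {missing.tolist()[:10]}")
    a = adg.reindex(expr.columns).to_numpy(float)
    rows = []
    for g in expr.index:
        r, p = pearson_with_pvalue(expr.loc[g].to_numpy(float), a)
        rows.append((g, r, p, p < p_threshold))
    return pd.DataFrame(rows, columns=["gene_id", "r", "p", "growth_correlated"])
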