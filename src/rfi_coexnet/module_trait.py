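"""Module-trait association: eigengene vs trait Pearson correlation.

A module is trait-specific when |r| > 0.4 AND p < 0.05 (both thresholds
configurable).  The grey (unassigned) pseudo-module is excluded.  No
multiple-testing correction is applied across modules at this stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import GREY

__all__ = ["ModuleTraitResult", "pearson_with_pvalue", "module_trait_correlations"]


@dataclass
class ModuleTraitResult:
    module: str
    trait: str
    r: float
    p: float
    n: int
    selected: bool


def pearson_with_pvalue(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided Student-t p-value.

    p is the two-sided tail of t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of
    freedom; |r| = 1 returns the smallest positive float.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("inputs must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, float(np.nextafter(0, 1))
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(min(p, 1.0))


def module_trait_correlations(
    eigengenes: pd.DataFrame,
    trait: pd.Series,
    trait_name: str = "RFI",
    r_threshold: float = 0.4,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Correlate every non-grey module eigengene with the trait.

    ``eigengenes`` is samples x modules, ``trait`` indexed by sample id.
    Returns a DataFrame with columns module, trait, r, p, n, selected.
    """
    missing = eigengenes.index.difference(trait.index)
    if len(missing):
        raise ValueError(f"trait missing for samples: {missing.tolist()[:10]}")
    t = trait.reindex(eigengenes.index).to_numpy(float)
    rows = []
    for module in eigengenes.columns:
        if module == GREY:
            continue
        r, p = pearson_with_pvalue(eigengenes[module].to_numpy(), t)
        rows.append(
            ModuleTraitResult(
                module=module, trait=trait_name, r=r, p=p, n=len(t),
                selected=bool(abs(r) > r_threshold and p < p_threshold),
            )
        )
    columns = ["module", "trait", "r", "p", "n", "selected"]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame([vars(r) for r in rows], columns=columns)
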