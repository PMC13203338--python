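"""Feed-efficiency phenotypes from individual feeding-trial records.

Each animal is housed individually, so its feed bookkeeping (initial feed
weight ``F1``, remaining feed ``Fr``, recovered uneaten feed ``F0``) and
body weights (``W1`` at stocking, ``W2`` at harvest) yield three primary
phenotypes:

* **ADG** — average daily gain, ``(W2 - W1) / duration`` (g/day)
* **DFI** — daily feed intake, ``(F1 - Fr - F0) / duration`` (g/day)
* **RFI** — residual feed intake, observed DFI minus the intake expected
  from maintenance and growth.

Expected intake follows the nonlinear allometric model

    DFI = b1 * MW**b2 + b3 * ADG

where ``MW = (W1 + W2) / 2`` is the mid-weight and ``MW**b2`` the metabolic
mid-weight.  A negative RFI means the animal eats less than expected for
its size and growth, i.e. it is the more feed-efficient animal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

__all__ = [
    "FeedingRecord",
    "PhenotypeRow",
    "RFIModelFit",
    "compute_adg",
    "compute_dfi",
    "compute_mw",
    "compute_phenotypes",
    "fit_expected_dfi",
    "compute_rfi",
    "select_extremes",
    "records_to_frame",
    "records_from_frame",
]


@dataclass(frozen=True)
class FeedingRecord:
    """One animal's weights and feed bookkeeping over the trial.

    All masses in grams, duration in days.
    """

    individual_id: str
    W1: float
    W2: float
    F1: float
    Fr: float
    F0: float
    duration: float = 42.0
    survived: bool = True

    def __post_init__(self) -> None:
        for name in ("W1", "W2", "F1", "Fr", "F0"):
            if getattr(self, name) < 0:
                raise ValueError(
                    f"{self.individual_id}: {name} must be non-negative, "
                    f"got {getattr(self, name)!r}"
                )
        if self.duration <= 0:
            raise ValueError(
                f"{self.individual_id}: duration must be positive, got {self.duration!r}"
            )
        if self.F1 < self.Fr + self.F0:
            raise ValueError(
                f"{self.individual_id}: feed bookkeeping violated, "
                f"F1={self.F1} < Fr+F0={self.Fr + self.F0}"
            )


@dataclass
class PhenotypeRow:
    individual_id: str
    ADG: float
    DFI: float
    MW: float
    expected_DFI: float = float("nan")
    RFI: float = float("nan")


@dataclass
class RFIModelFit:
    """Coefficients of the expected-intake model DFI = b1*MW^b2 + b3*ADG."""

    b1: float
    b2: float
    b3: float
    n_obs: int
    rss: float
    converged: bool
    rss_trace: list = field(default_factory=list, repr=False)

    def predict(self, mw: np.ndarray, adg: np.ndarray) -> np.ndarray:
        if not self.converged:
            raise RuntimeError("expected-intake model did not converge; refusing to predict")
        return self.b1 * np.asarray(mw, float) ** self.b2 + self.b3 * np.asarray(adg, float)


def compute_adg(record: FeedingRecord) -> float:
    """Average daily gain (g/day): (W2 - W1) / duration."""
    return (record.W2 - record.W1) / record.duration


def compute_dfi(record: FeedingRecord) -> float:
    """Observed daily feed intake (g/day): (F1 - Fr - F0) / duration."""
    return (record.F1 - record.Fr - record.F0) / record.duration


def compute_mw(record: FeedingRecord) -> float:
    """Mid-weight (g): arithmetic mean of initial and harvest body weight."""
    return (record.W1 + record.W2) / 2.0


def compute_phenotypes(records: Sequence[FeedingRecord]) -> list[PhenotypeRow]:
    """ADG/DFI/MW for every record (expected DFI and RFI left unfilled)."""
    return [
        PhenotypeRow(
            individual_id=r.individual_id,
            ADG=compute_adg(r),
            DFI=compute_dfi(r),
            MW=compute_mw(r),
        )
        for r in records
    ]


def _profiled_rss(b2: float, mw: np.ndarray, adg: np.ndarray, dfi: np.ndarray):
    """RSS profiled over (b1, b3): at fixed b2 the model is linear."""
    X = np.column_stack([mw**b2, adg])
    coef, _, _, _ = np.linalg.lstsq(X, dfi, rcond=None)
    resid = dfi - X @ coef
    return float(resid @ resid), coef


def fit_expected_dfi(
    rows: Sequence[PhenotypeRow],
    *,
    b2_init: float = 0.75,
    b2_bounds: tuple[float, float] = (0.05, 3.0),
    max_iter: int = 500,
    rss_rtol: float = 1e-10,
    step_tol: float = 1e-8,
) -> RFIModelFit:
    """Fit DFI = b1*MW^b2 + b3*ADG by nonlinear least squares.

    The model is linear in (b1, b3) given b2, so the fit profiles those two
    out analytically and minimises the one-dimensional profiled RSS over b2
    (variable projection).  This is deterministic, needs no starting guess
    for b1/b3, and converges from the standard metabolic-exponent start
    b2 = 0.75.

    Raises
    ------
    ValueError
        if fewer than 10 rows, or any MW <= 0.
    RuntimeError
        if the optimiser does not converge.
    """
    if len(rows) < 10:
        raise ValueError(f"need at least 10 rows to fit 3 coefficients, got {len(rows)}")
    mw = np.array([r.MW for r in rows], float)
    adg = np.array([r.ADG for r in rows], float)
    dfi = np.array([r.DFI for r in rows], float)
    if np.any(mw <= 0):
        raise ValueError("all mid-weights must be positive")

    trace: list[float] = []

    def objective(b2: float) -> float:
        rss, _ = _profiled_rss(b2, mw, adg, dfi)
        if not trace or rss < trace[-1]:
            trace.append(rss)
        return rss

    # Bracket around the warm start, then Brent with bounds.
    res = optimize.minimize_scalar(
        objective,
        bounds=b2_bounds,
        method="bounded",
        options={"xatol": step_tol, "maxiter": max_iter},
    )
    if not res.success:
        raise RuntimeError(f"expected-intake model failed to converge: {res.message}")
    # Polish: a second bounded pass localised at the optimum guards against
    # the coarse first bracket on flat profiles.
    lo = max(b2_bounds[0], res.x - 0.05)
    hi = min(b2_bounds[1], res.x + 0.05)
    res2 = optimize.minimize_scalar(
        objective, bounds=(lo, hi), method="bounded",
        options={"xatol": step_tol * 1e-2, "maxiter": max_iter},
    )
    b2 = float(res2.x if res2.fun <= res.fun else res.x)
    rss, (b1, b3) = _profiled_rss(b2, mw, adg, dfi)
    if not (0.3 < b2 < 1.2):
        logger.warning("fitted metabolic exponent b2=%.4f outside (0.3, 1.2)", b2)
    converged = bool(res.success and np.isfinite([b1, b2, b3]).all())
    if not converged:
        raise RuntimeError("expected-intake model produced non-finite coefficients")
    return RFIModelFit(
        b1=float(b1), b2=b2, b3=float(b3),
        n_obs=len(rows), rss=rss, converged=converged, rss_trace=trace,
    )


def compute_rfi(rows: Sequence[PhenotypeRow], fit: RFIModelFit) -> list[PhenotypeRow]:
    """Fill expected DFI and RFI = DFI - expected DFI on every row.

    The sign convention follows the field: negative RFI = eats less than
    expected = more efficient.
    """
    if not fit.converged:
        raise RuntimeError("refusing to compute RFI from a non-converged fit")
    out = []
    for r in rows:
        expected = fit.b1 * r.MW**fit.b2 + fit.b3 * r.ADG
        out.append(
            PhenotypeRow(
                individual_id=r.individual_id,
                ADG=r.ADG, DFI=r.DFI, MW=r.MW,
                expected_DFI=float(expected),
                RFI=float(r.DFI - expected),
            )
        )
    return out


def select_extremes(rows: Sequence[PhenotypeRow], k: int) -> tuple[list[str], list[str]]:
    """Extreme-RFI groups: (high-efficiency ids, low-efficiency ids).

    The k animals with the *lowest* RFI form the high-efficiency group and
    the k with the *highest* RFI the low-efficiency group.  Boundary ties
    are broken lexicographically by individual id, so the selection is
    deterministic.
    """
    if 2 * k > len(rows):
        raise ValueError(f"cannot select 2*{k} extremes from {len(rows)} rows")
    order = sorted(rows, key=lambda r: (r.RFI, r.individual_id))
    high_eff = [r.individual_id for r in order[:k]]
    low_eff = [r.individual_id for r in order[-k:]]
    return high_eff, low_eff


# ---------------------------------------------------------------------------
# I/O helpers

_RECORD_COLS = ["individual_id", "W1", "W2", "F1", "Fr", "F0", "duration", "survived"]


def records_to_frame(records: Sequence[FeedingRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [[r.individual_id, r.W1, r.W2, r.F1, r.Fr, r.F0, r.duration, r.survived]
         for r in records],
        columns=_RECORD_COLS,
    )


def records_from_frame(df: pd.DataFrame) -> list[FeedingRecord]:
    missing = set(_RECORD_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"records table missing columns: {sorted(missing)}")
    return [
        FeedingRecord(
            individual_id=str(row.individual_id),
            W1=float(row.W1), W2=float(row.W2),
            F1=float(row.F1), Fr=float(row.Fr), F0=float(row.F0),
            duration=float(row.duration), survived=bool(row.survived),
        )
        for row in df.itertuples(index=False)
    ]


def phenotypes_to_frame(rows: Sequence[PhenotypeRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [[r.individual_id, r.ADG, r.DFI, r.MW, r.expected_DFI, r.RFI] for r in rows],
        columns=["individual_id", "ADG", "DFI", "MW", "expected_DFI", "RFI"],
    )
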