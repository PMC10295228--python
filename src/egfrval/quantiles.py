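"""Quantile-regression prediction intervals of mGFR at eGFR decision thresholds.

Seven linear quantile models (levels 0.025, 0.10, 0.25, 0.50, 0.75, 0.90,
0.975) of measured GFR on estimated GFR are fitted independently by exact
minimization of the check (pinball) loss

    L_tau(a, b) = sum_i rho_tau(y_i - a - b*x_i),
    rho_tau(u) = u * (tau - 1[u < 0]),

cast as a linear program and solved with HiGHS.  Evaluating all seven
models at a clinical eGFR threshold yields the predicted mGFR percentile
band: the 95% prediction interval (p2.5-p97.5), the 80% (p10-p90) and the
50% (p25-p75) interval, plus flags for whether the band crosses an
adjacent KDIGO stage cutoff — the clinically relevant failure mode, since
a band that crosses a stage boundary means the estimate cannot pin down
the patient's CKD stage.

Independently fitted quantile lines may cross at a given threshold; a
crossing is reported as a warning with the offending levels and interval
widths are floored at zero, never silently reordered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .metrics import PairedSeries

logger = logging.getLogger("egfrval")

__all__ = [
    "QUANTILE_LEVELS",
    "QuantileFit",
    "QuantileModelSet",
    "PredictionInterval",
    "StageCrossing",
    "fit_quantile_models",
    "predict_quantiles",
    "stage_crossing",
    "pinball_loss",
]

#: The seven conditional-quantile levels fitted by default.
QUANTILE_LEVELS = (0.025, 0.10, 0.25, 0.50, 0.75, 0.90, 0.975)

#: KDIGO stage boundaries used for crossing checks (mL/min/1.73 m²).
STAGE_CUTOFFS = (15.0, 30.0, 45.0, 60.0, 90.0)


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class QuantileFit:
    """One fitted linear conditional-quantile model."""

    level: float
    intercept: float
    slope: float
    objective: float  # minimized check loss
    n: int

    def predict(self, x) -> float:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass(frozen=True)
class QuantileModelSet:
    """Independently fitted quantile models keyed by level."""

    fits: dict[float, QuantileFit]
    n: int
    predictor: str = "egfr"
    response: str = "mgfr"

    @property
    def levels(self) -> tuple[float, ...]:
        return tuple(sorted(self.fits))

    def predict_level(self, level: float, x) -> float:
        return float(self.fits[level].predict(x))


@dataclass(frozen=True)
class StageCrossing:
    """Whether a prediction band spills past the adjacent stage cutoffs."""

    threshold: float
    lower_cutoff: Optional[float]
    upper_cutoff: Optional[float]
    crosses_lower: Optional[bool]
    crosses_upper: Optional[bool]
    lower_margin: Optional[float]  # p2.5 − lower cutoff (negative => crossed by |margin|)
    upper_margin: Optional[float]  # upper cutoff − p97.5 (negative => crossed by |margin|)
    note: str = ""


@dataclass(frozen=True)
class PredictionInterval:
    """Predicted mGFR percentile band at one eGFR threshold."""

    threshold: float
    percentile_predictions: dict[float, float]
    width_95: float
    width_80: float
    width_50: float
    crossing: Optional[StageCrossing] = None
    quantile_crossing_levels: tuple[tuple[float, float], ...] = ()


def pinball_loss(tau: float, residuals: np.ndarray) -> float:
    """Check loss sum rho_tau(u) with rho_tau(u) = u*(tau - 1[u<0])."""
    u = np.asarray(residuals, dtype=float)
    return float(np.sum(u * (tau - (u < 0))))


def _fit_one(x: np.ndarray, y: np.ndarray, tau: float) -> QuantileFit:
    """Exact check-loss minimization over (intercept, slope) as an LP.

    Variables: a+, a-, b+, b-, u+ (n), u- (n); constraints
    y_i = (a+ - a-) + (b+ - b-) x_i + u+_i - u-_i; objective
    tau*sum(u+) + (1-tau)*sum(u-).
    """
    n = len(x)
    c = np.concatenate([[0.0, 0.0, 0.0, 0.0], np.full(n, tau), np.full(n, 1.0 - tau)])
    eye = sparse.eye(n, format="csc")
    ones = np.ones((n, 1))
    a_eq = sparse.hstack(
        [sparse.csc_matrix(ones), sparse.csc_matrix(-ones), sparse.csc_matrix(x[:, None]),
         sparse.csc_matrix(-x[:, None]), eye, -eye],
        format="csc",
    )
    res = linprog(c, A_eq=a_eq, b_eq=y, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - HiGHS is reliable on this LP
        raise FitError(f"quantile LP failed at tau={tau}: {res.message}")
    a = res.x[0] - res.x[1]
    b = res.x[2] - res.x[3]
    return QuantileFit(level=tau, intercept=float(a), slope=float(b), objective=float(res.fun), n=n)


def fit_quantile_models(
    series: PairedSeries, levels: Sequence[float] = QUANTILE_LEVELS
) -> QuantileModelSet:
    """Fit one linear quantile model of mGFR on eGFR per level.

    Each model is fitted independently by exact LP minimization of its
    check loss.  Requires n >= 20; tail levels (0.025/0.975) are flagged
    as unstable below n = 100.
    """
    x = series.egfr
    y = series.mgfr
    n = len(series)
    if n < 20:
        raise ValueError(f"quantile regression requires n >= 20, got {n}")
    if np.ptp(x) == 0.0:
        raise FitError("no identifiable slope: predictor (eGFR) has zero variance")
    extreme = [t for t in levels if min(t, 1 - t) <= 0.025]
    if n < 100 and extreme:
        logger.warning("W-TAIL-QUANTILE: n=%d < 100; tail quantile fits %s are unstable", n, extreme)
    fits = {float(t): _fit_one(x, y, float(t)) for t in levels}
    return QuantileModelSet(fits=fits, n=n)


def predict_quantiles(
    models: QuantileModelSet,
    threshold: float,
    stage_cutoffs: Sequence[float] = STAGE_CUTOFFS,
) -> PredictionInterval:
    """Evaluate every quantile model at an eGFR threshold.

    Returns the seven predicted mGFR percentiles, the 95/80/50% interval
    widths (floored at 0 if fitted quantile lines cross at this threshold,
    with the offending level pairs recorded), and the adjacent-stage
    crossing report when the threshold sits among the configured cutoffs.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    preds = {lvl: models.predict_level(lvl, threshold) for lvl in models.levels}

    crossings = []
    lv = sorted(preds)
    for lo, hi in zip(lv[:-1], lv[1:]):
        if preds[hi] < preds[lo] - 1e-9:
            crossings.append((lo, hi))
    if crossings:
        logger.warning(
            "W-QUANTILE-CROSSING: quantile lines cross at threshold %.6g for levels %s", threshold, crossings
        )

    def width(lo: float, hi: float) -> float:
        if lo in preds and hi in preds:
            return max(0.0, preds[hi] - preds[lo])
        return float("nan")

    pi = PredictionInterval(
        threshold=float(threshold),
        percentile_predictions=preds,
        width_95=width(0.025, 0.975),
        width_80=width(0.10, 0.90),
        width_50=width(0.25, 0.75),
        quantile_crossing_levels=tuple(crossings),
    )
    cr = stage_crossing(pi, stage_cutoffs)
    return PredictionInterval(
        threshold=pi.threshold,
        percentile_predictions=pi.percentile_predictions,
        width_95=pi.width_95,
        width_80=pi.width_80,
        width_50=pi.width_50,
        crossing=cr,
        quantile_crossing_levels=pi.quantile_crossing_levels,
    )


def stage_crossing(
    pi: PredictionInterval, stage_cutoffs: Sequence[float] = STAGE_CUTOFFS
) -> StageCrossing:
    """Flag whether the 95% band spills past the adjacent stage cutoffs.

    The adjacent cutoffs are the largest configured cutoff strictly below
    the threshold and the smallest strictly above it.  The margins report
    how far the band edge sits inside the cutoff (negative = crossed by
    that amount, in mL/min/1.73 m²).
    """
    cuts = sorted(float(c) for c in stage_cutoffs)
    below = [c for c in cuts if c < pi.threshold]
    above = [c for c in cuts if c > pi.threshold]
    lower = below[-1] if below else None
    upper = above[0] if above else None
    if lower is None and upper is None:
        return StageCrossing(pi.threshold, None, None, None, None, None, None, note="no adjacent cutoff")
    p_lo = pi.percentile_predictions.get(0.025)
    p_hi = pi.percentile_predictions.get(0.975)
    lower_margin = crosses_lower = None
    upper_margin = crosses_upper = None
    if lower is not None and p_lo is not None:
        lower_margin = p_lo - lower
        crosses_lower = bool(lower_margin < 0)
    if upper is not None and p_hi is not None:
        upper_margin = upper - p_hi
        crosses_upper = bool(upper_margin < 0)
    return StageCrossing(
        threshold=pi.threshold,
        lower_cutoff=lower,
        upper_cutoff=upper,
        crosses_lower=crosses_lower,
        crosses_upper=crosses_upper,
        lower_margin=lower_margin,
        upper_margin=upper_margin,
    )
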