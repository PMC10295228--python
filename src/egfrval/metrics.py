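"""Method-comparison statistics for eGFR validation.

Implements the standard agreement metrics used to validate a GFR-estimating
equation against measured GFR (mGFR):

* **bias** — median of the per-subject signed difference eGFR − mGFR;
* **precision** — interquartile range (IQR) of that difference;
* **accuracy** — Px, the percentage of subjects whose eGFR lies within x%
  of mGFR (P15/P20/P30 by convention), and the regression-error-
  characteristic (REC) curve that traces Px over a dense tolerance grid;

together with their inferential machinery: percentile-bootstrap confidence
intervals with subject-level (optionally cluster) resampling, a bootstrap
test for IQR differences, Wilcoxon signed-rank and rank-sum tests with
exact small-sample enumeration, McNemar's test on paired within-tolerance
classifications, Benjamini-Hochberg multiplicity adjustment, and the
normal-approximation sample-size formulas for a proportion.

Quantile convention: quartiles use linear interpolation between order
statistics (numpy's default), the common default of R's ``quantile`` —
pinned because IQR values are conventionally reported to 0.1 precision.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("egfrval")

__all__ = [
    "BootstrapSpec",
    "PairedSeries",
    "BiasResult",
    "PrecisionResult",
    "AccuracyResult",
    "PairwiseTestResult",
    "RECCurve",
    "SubgroupComparison",
    "signed_bias",
    "precision_iqr",
    "iqr_difference_test",
    "accuracy_px",
    "accuracy_mcnemar",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "bh_adjust",
    "rec_curve",
    "subgroup_bias_table",
    "sample_size_proportion",
]

#: Exact-enumeration threshold for the Wilcoxon tests (per stratum / post
#: zero-drop); above it the normal approximation with tie correction is used.
EXACT_N_MAX = 10


@dataclass(frozen=True)
class BootstrapSpec:
    """Percentile-bootstrap configuration.

    ``replicates`` defaults to 2000; resampling is at the subject (row)
    level, or at the cluster level when ``cluster_by`` ids are attached to
    the series and ``cluster_by_subject`` is set.  The seed is recorded in
    every report for reproducibility.
    """

    replicates: int = 2000
    seed: Optional[int] = None
    ci_level: float = 0.95
    cluster_by_subject: bool = False

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    @property
    def ci_quantiles(self) -> tuple[float, float]:
        a = (1.0 - self.ci_level) / 2.0
        return a, 1.0 - a


@dataclass(frozen=True)
class PairedSeries:
    """Row-aligned eGFR / mGFR vectors for one equation (mL/min/1.73 m²)."""

    egfr: np.ndarray
    mgfr: np.ndarray
    name: str = ""
    subject_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "egfr", np.asarray(self.egfr, dtype=float))
        object.__setattr__(self, "mgfr", np.asarray(self.mgfr, dtype=float))
        if self.egfr.ndim != 1 or self.mgfr.ndim != 1:
            raise ValueError("egfr and mgfr must be 1-D vectors")
        if len(self.egfr) != len(self.mgfr):
            raise ValueError("egfr and mgfr must have equal length")
        if len(self.egfr) < 1:
            raise ValueError("series must contain at least one pair")
        if np.any(~np.isfinite(self.egfr)) or np.any(~np.isfinite(self.mgfr)):
            raise ValueError("series must be free of missing values after filtering")
        bad = np.flatnonzero(self.mgfr <= 0)
        if bad.size:
            raise ValueError(f"mgfr must be strictly positive; offending rows: {bad.tolist()}")

    def __len__(self) -> int:
        return len(self.egfr)

    @property
    def diff(self) -> np.ndarray:
        """Signed differences eGFR − mGFR."""
        return self.egfr - self.mgfr


@dataclass(frozen=True)
class BiasResult:
    median_bias: float
    ci_low: float
    ci_high: float
    n: int


@dataclass(frozen=True)
class PrecisionResult:
    iqr: float
    ci_low: float
    ci_high: float
    n: int


@dataclass(frozen=True)
class AccuracyResult:
    tolerance_pct: float
    proportion_pct: float
    ci_low: float
    ci_high: float
    n: int


@dataclass(frozen=True)
class PairwiseTestResult:
    metric: str
    pair: tuple[str, str]
    statistic: float
    p_raw: float
    method: str
    p_adjusted: Optional[float] = None
    note: str = ""


@dataclass(frozen=True)
class RECCurve:
    tolerance_grid: np.ndarray
    fraction_within: np.ndarray  # percent, aligned with tolerance_grid


@dataclass(frozen=True)
class SubgroupComparison:
    condition: str
    equation: str
    bias_with: BiasResult
    bias_without: BiasResult
    p_value: float
    eligible: bool


# ---------------------------------------------------------------------------
# bootstrap helpers


def _iqr(x: np.ndarray, axis=None) -> np.ndarray:
    q1, q3 = np.percentile(x, [25.0, 75.0], axis=axis, method="linear")
    return q3 - q1


def _replicate_indices(boot: BootstrapSpec, n: int, subject_ids: Optional[np.ndarray]):
    """Yield one index array per bootstrap replicate (subject or cluster level)."""
    rng = boot.rng()
    if boot.cluster_by_subject and subject_ids is not None:
        ids = np.asarray(subject_ids)
        uniq = np.unique(ids)
        members = {u: np.flatnonzero(ids == u) for u in uniq}
        for _ in range(boot.replicates):
            chosen = rng.choice(uniq, size=len(uniq), replace=True)
            yield np.concatenate([members[u] for u in chosen])
    else:
        for _ in range(boot.replicates):
            yield rng.integers(0, n, size=n)


def _bootstrap_vector_stat(values: np.ndarray, stat, boot: BootstrapSpec, subject_ids=None) -> np.ndarray:
    """Replicate statistics of a 1-D sample under subject resampling."""
    n = len(values)
    if boot.cluster_by_subject and subject_ids is not None:
        reps = np.array([stat(values[idx]) for idx in _replicate_indices(boot, n, subject_ids)])
    else:
        idx = boot.rng().integers(0, n, size=(boot.replicates, n))
        reps = stat(values[idx], axis=1) if _supports_axis(stat) else np.array([stat(values[i]) for i in idx])
    return reps


def _supports_axis(stat) -> bool:
    return stat in (np.median, np.mean, _iqr)


def _percentile_ci(reps: np.ndarray, boot: BootstrapSpec) -> tuple[float, float]:
    lo, hi = boot.ci_quantiles
    return float(np.quantile(reps, lo)), float(np.quantile(reps, hi))


# ---------------------------------------------------------------------------
# point metrics


def signed_bias(series: PairedSeries, boot: Optional[BootstrapSpec] = None) -> BiasResult:
    """Median signed bias eGFR − mGFR with a percentile-bootstrap CI."""
    boot = boot or BootstrapSpec()
    if boot.replicates < 1:
        raise ValueError("boot.replicates must be >= 1")
    d = series.diff
    est = float(np.median(d))
    reps = _bootstrap_vector_stat(d, np.median, boot, series.subject_ids)
    lo, hi = _percentile_ci(reps, boot)
    return BiasResult(est, min(lo, est), max(hi, est), len(series))


def precision_iqr(series: PairedSeries, boot: Optional[BootstrapSpec] = None) -> PrecisionResult:
    """IQR of the signed differences (Q3 − Q1, linear-interpolation quartiles)."""
    boot = boot or BootstrapSpec()
    d = series.diff
    if len(d) < 2:
        raise ValueError("precision requires at least 2 pairs")
    if len(d) < 8:
        logger.warning("W-SMALL-N: IQR precision on n=%d (< 8) is unstable", len(d))
    est = float(_iqr(d))
    reps = _bootstrap_vector_stat(d, _iqr, boot, series.subject_ids)
    lo, hi = _percentile_ci(reps, boot)
    return PrecisionResult(est, min(lo, est), max(hi, est), len(series))


def accuracy_px(series: PairedSeries, x: float, boot: Optional[BootstrapSpec] = None) -> AccuracyResult:
    """Px accuracy: percent of subjects with |eGFR − mGFR| ≤ (x/100)·mGFR.

    The tolerance boundary is inclusive.
    """
    if x <= 0:
        raise ValueError("tolerance x must be > 0 (percent)")
    boot = boot or BootstrapSpec()
    within = within_tolerance(series, x).astype(float)
    est = float(100.0 * within.mean())
    reps = 100.0 * _bootstrap_vector_stat(within, np.mean, boot, series.subject_ids)
    lo, hi = _percentile_ci(reps, boot)
    return AccuracyResult(float(x), est, max(0.0, min(lo, est)), min(100.0, max(hi, est)), len(series))


def within_tolerance(series: PairedSeries, x: float) -> np.ndarray:
    """Boolean vector: |eGFR − mGFR| ≤ (x/100)·mGFR (boundary inclusive)."""
    return np.abs(series.diff) <= (x / 100.0) * series.mgfr


def rec_curve(series: PairedSeries, grid: Sequence[float]) -> RECCurve:
    """REC curve: Px point estimates over an ascending tolerance grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("tolerance grid must be non-empty")
    if np.any(grid <= 0) or np.any(np.diff(grid) < 0):
        raise ValueError("tolerance grid must be positive and ascending")
    rel = np.abs(series.diff) / series.mgfr * 100.0
    frac = np.array([100.0 * np.mean(rel <= g) for g in grid])
    return RECCurve(grid, frac)


# ---------------------------------------------------------------------------
# paired tests


def iqr_difference_test(
    a: PairedSeries, b: PairedSeries, boot: Optional[BootstrapSpec] = None
) -> PairwiseTestResult:
    """Bootstrap test for a difference in IQR precision between two equations.

    Subjects are resampled jointly (paired resampling); the replicate
    statistic is IQR_a − IQR_b and the two-sided p-value is the sign-share
    rule 2·min(share ≤ 0, share ≥ 0), floored at 1/replicates.
    """
    boot = boot or BootstrapSpec()
    if len(a) != len(b):
        raise ValueError("series must be row-aligned on the same subjects")
    da, db = a.diff, b.diff
    obs = float(_iqr(da) - _iqr(db))
    if boot.cluster_by_subject and a.subject_ids is not None:
        reps = np.array([_iqr(da[i]) - _iqr(db[i]) for i in _replicate_indices(boot, len(a), a.subject_ids)])
    else:
        idx = boot.rng().integers(0, len(a), size=(boot.replicates, len(a)))
        reps = _iqr(da[idx], axis=1) - _iqr(db[idx], axis=1)
    share_le = np.mean(reps <= 0.0)
    share_ge = np.mean(reps >= 0.0)
    p = float(np.clip(2.0 * min(share_le, share_ge), 1.0 / boot.replicates, 1.0))
    return PairwiseTestResult(
        metric="precision", pair=(a.name, b.name), statistic=obs, p_raw=p, method="bootstrap_iqr"
    )


def accuracy_mcnemar(
    a: PairedSeries, b: PairedSeries, x: float, method: str = "auto"
) -> PairwiseTestResult:
    """McNemar's test on paired within-tolerance classifications at Px.

    ``method``: ``"chi2"`` is the continuity-corrected chi-squared on the
    discordant counts, ``"exact"`` the binomial conditional test; ``"auto"``
    selects exact when the discordant total is below 25.
    """
    if len(a) != len(b):
        raise ValueError("series must be row-aligned on the same subjects")
    wa = within_tolerance(a, x)
    wb = within_tolerance(b, x)
    n10 = int(np.sum(wa & ~wb))  # within for A only
    n01 = int(np.sum(~wa & wb))  # within for B only
    nd = n10 + n01
    metric = f"accuracy:{x:g}"
    if nd == 0:
        logger.info("N-MCNEMAR-ZERO: no discordant pairs at P%g; statistic undefined, p = 1", x)
        return PairwiseTestResult(metric, (a.name, b.name), 0.0, 1.0, "mcnemar", note="no discordant pairs")
    if method == "auto":
        method = "exact" if nd < 25 else "chi2"
    if method == "exact":
        k = min(n10, n01)
        p = float(min(1.0, 2.0 * stats.binom.cdf(k, nd, 0.5)))
        return PairwiseTestResult(metric, (a.name, b.name), float(k), p, "mcnemar_exact")
    stat = (abs(n10 - n01) - 1.0) ** 2 / nd
    p = float(stats.chi2.sf(stat, df=1))
    return PairwiseTestResult(metric, (a.name, b.name), float(stat), p, "mcnemar")


def _exact_two_sided_p(stat_all: np.ndarray, stat_obs: float, center: float) -> float:
    """Two-sided exact p as the share of the null distribution at least as
    far from its center as the observed statistic (symmetric-distance rule)."""
    eps = 1e-9
    return float(np.mean(np.abs(stat_all - center) >= abs(stat_obs - center) - eps))


def _signed_rank_exact_p(d: np.ndarray) -> tuple[float, float]:
    """Exact signed-rank test by enumeration of all sign assignments."""
    ranks = stats.rankdata(np.abs(d))
    t_obs = float(ranks[d > 0].sum())
    n = len(d)
    masks = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
    t_all = masks @ ranks
    center = ranks.sum() / 2.0
    return t_obs, _exact_two_sided_p(t_all, t_obs, center)


def wilcoxon_signed_rank(a: PairedSeries, b: PairedSeries) -> PairwiseTestResult:
    """Wilcoxon signed-rank test on per-subject bias_a − bias_b.

    Zero differences are dropped (classic treatment); ties get average
    ranks.  Exact enumeration of sign assignments for n ≤ 10 after the
    zero-drop, normal approximation with tie correction otherwise.
    """
    if len(a) != len(b):
        raise ValueError("series must be row-aligned on the same subjects")
    d = a.diff - b.diff
    d = d[d != 0.0]
    if len(d) == 0:
        logger.info("N-WILCOXON-ZERO: all paired differences are zero; p = 1")
        return PairwiseTestResult("bias", (a.name, b.name), 0.0, 1.0, "wilcoxon_signed_rank",
                                  note="all differences zero")
    if len(d) <= EXACT_N_MAX:
        t_obs, p = _signed_rank_exact_p(d)
        return PairwiseTestResult("bias", (a.name, b.name), t_obs, p, "wilcoxon_signed_rank_exact")
    res = stats.wilcoxon(d, zero_method="wilcox", correction=False, alternative="two-sided", method="approx")
    return PairwiseTestResult("bias", (a.name, b.name), float(res.statistic), float(res.pvalue),
                              "wilcoxon_signed_rank")


def _rank_sum_exact_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact rank-sum test by enumeration of all group assignments."""
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    t_obs = float(ranks[:n].sum())
    center = n * (n + m + 1) / 2.0
    eps = 1e-9
    hits = total = 0
    for comb in combinations(range(n + m), n):
        t = ranks[list(comb)].sum()
        total += 1
        if abs(t - center) >= abs(t_obs - center) - eps:
            hits += 1
    return t_obs, hits / total


def wilcoxon_rank_sum(with_group: Sequence[float], without_group: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value comparing two bias distributions.

    Exact enumeration when both groups have ≤ 10 observations; otherwise the
    normal approximation with tie correction (continuity-corrected).
    """
    x = np.asarray(with_group, dtype=float)
    y = np.asarray(without_group, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if len(x) <= EXACT_N_MAX and len(y) <= EXACT_N_MAX:
        _, p = _rank_sum_exact_p(x, y)
        return float(p)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", use_continuity=True)
    return float(res.pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def apply_bh_family(tests: Sequence[PairwiseTestResult]) -> list[PairwiseTestResult]:
    """Attach BH-adjusted p-values to a family of pairwise tests."""
    if not tests:
        return []
    adj = bh_adjust([t.p_raw for t in tests])
    return [replace(t, p_adjusted=float(a)) for t, a in zip(tests, adj)]


# ---------------------------------------------------------------------------
# subgroup analysis


def subgroup_bias_table(
    cohort: pd.DataFrame,
    egfr_columns: Mapping[str, str],
    flags: Sequence[str],
    mgfr_column: str = "mgfr",
    min_size: int = 25,
    boot: Optional[BootstrapSpec] = None,
) -> list[SubgroupComparison]:
    """Stratified bias comparison per (condition flag, equation) pair.

    For each flag, subjects are split into with/without strata; each
    stratum's median bias (with bootstrap CI) is computed per equation, and
    the strata are compared with the Wilcoxon rank-sum test.  Comparisons
    whose flag-positive stratum has ≤ ``min_size`` subjects are still
    computed but marked ineligible.  Flags with a single stratum are
    skipped with a logged note.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    boot = boot or BootstrapSpec()
    out: list[SubgroupComparison] = []
    for flag in flags:
        if flag not in cohort.columns:
            raise KeyError(f"flag column {flag!r} not in cohort")
        fl = cohort[flag].astype("boolean")
        for eq_name, col in egfr_columns.items():
            avail = cohort[col].notna() & cohort[mgfr_column].notna() & fl.notna()
            sub = cohort.loc[avail]
            yes = sub[fl.loc[avail].astype(bool)]
            no = sub[~fl.loc[avail].astype(bool)]
            if len(yes) == 0 or len(no) == 0:
                logger.info("N-SUBGROUP-SKIP: flag %r has a single stratum; comparison skipped", flag)
                continue
            s_yes = PairedSeries(yes[col].to_numpy(), yes[mgfr_column].to_numpy(), name=f"{eq_name}|{flag}=yes")
            s_no = PairedSeries(no[col].to_numpy(), no[mgfr_column].to_numpy(), name=f"{eq_name}|{flag}=no")
            p = wilcoxon_rank_sum(s_yes.diff, s_no.diff)
            out.append(
                SubgroupComparison(
                    condition=flag,
                    equation=eq_name,
                    bias_with=signed_bias(s_yes, boot),
                    bias_without=signed_bias(s_no, boot),
                    p_value=p,
                    eligible=len(yes) > min_size,
                )
            )
    return out


def subgroup_table_frame(rows: Sequence[SubgroupComparison]) -> pd.DataFrame:
    """Flatten subgroup comparisons into a tidy DataFrame (one row per pair)."""
    recs = []
    for r in rows:
        recs.append(
            {
                "condition": r.condition,
                "equation": r.equation,
                "n_with": r.bias_with.n,
                "bias_with": r.bias_with.median_bias,
                "bias_with_ci_low": r.bias_with.ci_low,
                "bias_with_ci_high": r.bias_with.ci_high,
                "n_without": r.bias_without.n,
                "bias_without": r.bias_without.median_bias,
                "bias_without_ci_low": r.bias_without.ci_low,
                "bias_without_ci_high": r.bias_without.ci_high,
                "p_value": r.p_value,
                "eligible": r.eligible,
            }
        )
    return pd.DataFrame.from_records(recs)


# ---------------------------------------------------------------------------
# design-stage sample size


def sample_size_proportion(
    expected_accuracy: float,
    margin: float,
    alpha: float = 0.05,
    power: float = 0.90,
    method: str = "ci_width",
) -> int:
    """Normal-approximation sample size for estimating or testing a proportion.

    ``method="ci_width"``: n = z²·p(1−p)/d² — the size at which a two-sided
    (1−alpha) confidence interval for the proportion has half-width ``margin``.

    ``method="test"``: one-sample test of p against p0 = p − margin at
    two-sided level alpha with the given power:
    n = (z_{1−α/2}·√(p0·q0) + z_{1−β}·√(p·q))² / margin².

    Both return the ceiling; neither is tied to a specific software's
    rounding conventions.
    """
    for name, v in (("expected_accuracy", expected_accuracy), ("alpha", alpha), ("power", power)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must lie in (0, 1), got {v}")
    if not 0.0 < margin < 1.0:
        raise ValueError("margin must lie in (0, 1)")
    if margin >= min(expected_accuracy, 1.0 - expected_accuracy):
        raise ValueError("margin must be smaller than the proportion's distance to 0 and to 1")
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    p1 = expected_accuracy
    if method == "ci_width":
        n = z_a**2 * p1 * (1.0 - p1) / margin**2
    elif method == "test":
        z_b = stats.norm.ppf(power)
        p0 = p1 - margin
        n = (z_a * math.sqrt(p0 * (1.0 - p0)) + z_b * math.sqrt(p1 * (1.0 - p1))) ** 2 / margin**2
    else:
        raise ValueError("method must be 'ci_width' or 'test'")
    return int(math.ceil(n - 1e-12))
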