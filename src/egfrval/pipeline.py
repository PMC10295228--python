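"""End-to-end validation analysis: equations → metrics → intervals → reports.

``run_analysis`` evaluates the configured eGFR equations on a cohort,
computes the full method-comparison report (median bias, IQR precision,
Px accuracy with bootstrap CIs; pairwise Wilcoxon / bootstrap-IQR /
McNemar tests with Benjamini-Hochberg adjustment per metric family), REC
curves, per-equation quantile-regression prediction intervals at the CKD
decision thresholds, and the stratified subgroup bias table.  The result
is a machine-readable JSON bundle; the table renderers read the bundle
fields verbatim (no recomputation on the render path), so every number in
a rendered table equals the corresponding bundle entry.

Determinism contract: given the same cohort, configuration, and seed the
emitted JSON bundle is byte-identical.  All randomness (bootstrap
resampling) flows from the single configured seed through a fixed
derivation order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .equations import evaluate_equation, get_equation_spec
from .io import CohortTable, filter_valid
from .metrics import (
    BootstrapSpec,
    PairedSeries,
    accuracy_mcnemar,
    accuracy_px,
    apply_bh_family,
    iqr_difference_test,
    precision_iqr,
    rec_curve,
    signed_bias,
    subgroup_bias_table,
    subgroup_table_frame,
    wilcoxon_signed_rank,
)
from .quantiles import QUANTILE_LEVELS, fit_quantile_models, predict_quantiles

logger = logging.getLogger("egfrval")

__all__ = ["RunConfig", "run_analysis", "render_performance_table", "render_subgroup_table", "bundle_to_json"]

#: canonical short column names for the shipped equations
EQUATION_COLUMNS = {"ckd_epi_2021_cr": "egfr_cr", "ckd_epi_2021_crcys": "egfr_crcys"}

DEFAULT_FLAGS = (
    "ckd",
    "kidney_transplant",
    "hypertension",
    "hyperlipidemia",
    "immunosuppressives",
    "corticosteroids",
    "beta_blockers",
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end analysis run."""

    seed: int = 0
    equations: tuple[str, ...] = ("ckd_epi_2021_cr", "ckd_epi_2021_crcys")
    external_columns: tuple[str, ...] = ("egfr_external",)
    tolerances: tuple[float, ...] = (15.0, 20.0, 30.0)
    rec_grid_max: float = 60.0
    pi_thresholds: tuple[float, ...] = (45.0, 60.0, 90.0)
    quantile_levels: tuple[float, ...] = QUANTILE_LEVELS
    subgroup_flags: tuple[str, ...] = DEFAULT_FLAGS
    min_subgroup_size: int = 25
    bootstrap_replicates: int = 2000
    ci_level: float = 0.95
    cluster_by_subject: bool = False
    scr_umol_per_l: bool = False

    def __post_init__(self) -> None:
        tol = tuple(self.tolerances)
        if any(t <= 0 for t in tol) or list(tol) != sorted(tol):
            raise ValueError("tolerances must be positive and ascending")
        if any(t <= 0 for t in self.pi_thresholds):
            raise ValueError("PI thresholds must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        for k in ("equations", "external_columns", "tolerances", "pi_thresholds", "quantile_levels", "subgroup_flags"):
            if k in kwargs and kwargs[k] is not None:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _egfr_column(name: str) -> str:
    return EQUATION_COLUMNS.get(name, f"egfr_{name}")


def _evaluate_equations(df: pd.DataFrame, config: RunConfig) -> dict[str, str]:
    """Add equation eGFR columns (available-case); return {label: column}."""
    columns: dict[str, str] = {}
    for name in config.equations:
        spec = get_equation_spec(name)
        needed = ["scr_mg_dl", "age", "sex"] + (["scys_mg_l"] if spec.uses_cystatin else [])
        if any(c not in df.columns for c in needed):
            logger.warning("W-EQ-SKIP: equation %s skipped, cohort lacks columns %s",
                           name, [c for c in needed if c not in df.columns])
            continue
        avail = np.ones(len(df), dtype=bool)
        for c in needed:
            if c != "sex":
                avail &= df[c].notna().to_numpy()
        if not avail.any():
            logger.warning("W-EQ-SKIP: equation %s skipped, no complete rows", name)
            continue
        col = _egfr_column(name)
        out = np.full(len(df), np.nan)
        sub = df.loc[avail]
        out[avail] = evaluate_equation(
            name,
            scr=sub["scr_mg_dl"].to_numpy(),
            age=sub["age"].to_numpy(),
            sex=sub["sex"].to_numpy(),
            scys=sub["scys_mg_l"].to_numpy() if spec.uses_cystatin else None,
            scr_umol_per_l=config.scr_umol_per_l,
        )
        df[col] = out
        columns[name] = col
    for col in config.external_columns:
        if col in df.columns:
            columns[col] = col
        else:
            logger.warning("W-EXT-SKIP: external column %r not present; skipped", col)
    return columns


def _series_for(df: pd.DataFrame, col: str, label: str) -> Optional[PairedSeries]:
    avail = df[col].notna() & df["mgfr"].notna()
    if not avail.any():
        return None
    sub = df.loc[avail]
    return PairedSeries(
        egfr=sub[col].to_numpy(),
        mgfr=sub["mgfr"].to_numpy(),
        name=label,
        subject_ids=sub["subject_id"].to_numpy() if "subject_id" in sub.columns else None,
    )


def run_analysis(table: Union[CohortTable, pd.DataFrame], config: RunConfig) -> dict:
    """Run the full validation analysis; returns the JSON-serializable bundle."""
    table, exclusions = filter_valid(table)
    df = table.df.copy()
    seed_stream = np.random.default_rng(config.seed)

    def next_boot() -> BootstrapSpec:
        return BootstrapSpec(
            replicates=config.bootstrap_replicates,
            seed=int(seed_stream.integers(2**31)),
            ci_level=config.ci_level,
            cluster_by_subject=config.cluster_by_subject,
        )

    columns = _evaluate_equations(df, config)
    if not columns:
        raise ValueError("no equation or external eGFR column could be resolved on this cohort")

    series = {}
    for label, col in columns.items():
        s = _series_for(df, col, label)
        if s is not None:
            series[label] = s

    comparison = {}
    for label, s in series.items():
        bias = signed_bias(s, next_boot())
        prec = precision_iqr(s, next_boot())
        acc = {f"p{t:g}": asdict(accuracy_px(s, t, next_boot())) for t in config.tolerances}
        comparison[label] = {"n": len(s), "bias": asdict(bias), "precision": asdict(prec), "accuracy": acc}

    labels = list(series)
    pairs = [(labels[i], labels[j]) for i in range(len(labels)) for j in range(i + 1, len(labels))]

    def joint(a: str, b: str) -> Optional[tuple[PairedSeries, PairedSeries]]:
        # paired tests need the rows where BOTH columns are available
        avail = df[columns[a]].notna() & df[columns[b]].notna() & df["mgfr"].notna()
        if not avail.any():
            return None
        sub = df.loc[avail]
        ids = sub["subject_id"].to_numpy() if "subject_id" in sub.columns else None
        return (
            PairedSeries(sub[columns[a]].to_numpy(), sub["mgfr"].to_numpy(), a, subject_ids=ids),
            PairedSeries(sub[columns[b]].to_numpy(), sub["mgfr"].to_numpy(), b, subject_ids=ids),
        )

    pairwise: dict[str, list] = {}
    fams: dict[str, list] = {"bias": [], "precision": []}
    for t in config.tolerances:
        fams[f"accuracy_p{t:g}"] = []
    for a, b in pairs:
        pair_series = joint(a, b)
        if pair_series is None:
            logger.warning("W-PAIR-SKIP: no jointly available rows for %s vs %s", a, b)
            continue
        sa, sb = pair_series
        fams["bias"].append(wilcoxon_signed_rank(sa, sb))
        fams["precision"].append(iqr_difference_test(sa, sb, next_boot()))
        for t in config.tolerances:
            fams[f"accuracy_p{t:g}"].append(accuracy_mcnemar(sa, sb, t))
    for fam, tests in fams.items():
        pairwise[fam] = [asdict(t) for t in apply_bh_family(tests)]

    grid = [float(g) for g in np.arange(1.0, config.rec_grid_max + 0.5)]
    rec = {}
    for label, s in series.items():
        c = rec_curve(s, grid)
        rec[label] = {"tolerance_pct": list(c.tolerance_grid), "fraction_within_pct": list(c.fraction_within)}

    prediction_intervals = {}
    for label, s in series.items():
        if len(s) < 20:
            logger.warning("W-PI-SKIP: %s has n=%d < 20; quantile models skipped", label, len(s))
            continue
        models = fit_quantile_models(s, config.quantile_levels)
        entries = []
        for thr in config.pi_thresholds:
            pi = predict_quantiles(models, thr)
            entries.append(
                {
                    "threshold": pi.threshold,
                    "percentile_predictions": {f"{lvl:g}": v for lvl, v in pi.percentile_predictions.items()},
                    "width_95": pi.width_95,
                    "width_80": pi.width_80,
                    "width_50": pi.width_50,
                    "quantile_crossing_levels": [list(c) for c in pi.quantile_crossing_levels],
                    "stage_crossing": asdict(pi.crossing) if pi.crossing else None,
                }
            )
        prediction_intervals[label] = {
            "n": models.n,
            "models": {
                f"{lvl:g}": {"intercept": f.intercept, "slope": f.slope, "objective": f.objective}
                for lvl, f in models.fits.items()
            },
            "thresholds": entries,
        }

    flags_present = [f for f in config.subgroup_flags if f in df.columns]
    sub_rows = subgroup_bias_table(
        df, {l: c for l, c in columns.items() if l in series}, flags_present,
        min_size=config.min_subgroup_size, boot=next_boot(),
    )
    subgroups = [
        {
            "condition": r.condition,
            "equation": r.equation,
            "bias_with": asdict(r.bias_with),
            "bias_without": asdict(r.bias_without),
            "p_value": r.p_value,
            "eligible": r.eligible,
        }
        for r in sub_rows
    ]

    bundle = {
        "meta": {
            "package": "egfrval",
            "version": __version__,
            "seed": config.seed,
            "bootstrap_replicates": config.bootstrap_replicates,
            "ci_level": config.ci_level,
            "n_analyzed": int(len(df)),
            "n_excluded": len(exclusions),
            "exclusions": exclusions,
            "provenance": {k: v for k, v in table.provenance.items()},
            "columns": columns,
        },
        "comparison": comparison,
        "pairwise_tests": pairwise,
        "rec_curves": rec,
        "prediction_intervals": prediction_intervals,
        "subgroups": subgroups,
    }
    return bundle


def bundle_to_json(bundle: dict) -> str:
    """Canonical JSON rendering of a result bundle (byte-stable for a seed)."""
    return json.dumps(bundle, sort_keys=True, indent=2, allow_nan=True)


# ---------------------------------------------------------------------------
# report rendering (reads bundle fields verbatim; no recomputation)


def _stars(p: Optional[float]) -> str:
    if p is None:
        return ""
    if p < 0.001:
        return " ***"
    if p < 0.01:
        return " **"
    if p < 0.05:
        return " *"
    return ""


def _md_table(header: list[str], rows: list[list[str]]) -> str:
    lines = ["| " + " | ".join(header) + " |", "|" + "|".join(["---"] * len(header)) + "|"]
    lines += ["| " + " | ".join(r) + " |" for r in rows]
    return "\n".join(lines)


def render_performance_table(bundle: dict, fmt: str = "md", reference: Optional[str] = None) -> str:
    """Performance summary (bias / precision / Px per equation) with CIs.

    Significance stars annotate the BH-adjusted p-value of each equation's
    pairwise test against the ``reference`` column (default: the last
    column, conventionally the externally supplied estimate).
    """
    comp = bundle["comparison"]
    labels = list(comp)
    reference = reference or labels[-1]

    def pair_p(fam: str, label: str) -> Optional[float]:
        for t in bundle["pairwise_tests"].get(fam, []):
            if set(t["pair"]) == {label, reference} and label != reference:
                return t["p_adjusted"]
        return None

    rows = []
    for label in labels:
        c = comp[label]
        b, p = c["bias"], c["precision"]
        row = [
            label,
            str(c["n"]),
            f"{b['median_bias']:.1f} ({b['ci_low']:.1f}; {b['ci_high']:.1f}){_stars(pair_p('bias', label))}",
            f"{p['iqr']:.1f} ({p['ci_low']:.1f}; {p['ci_high']:.1f}){_stars(pair_p('precision', label))}",
        ]
        for key, a in c["accuracy"].items():
            fam = f"accuracy_{key}"
            row.append(
                f"{a['proportion_pct']:.1f} ({a['ci_low']:.1f}; {a['ci_high']:.1f}){_stars(pair_p(fam, label))}"
            )
        rows.append(row)
    acc_heads = [f"{k.upper()} % (95% CI)" for k in next(iter(comp.values()))["accuracy"]]
    header = ["equation", "n", "median bias (95% CI)", "precision IQR (95% CI)"] + acc_heads
    if fmt == "csv":
        return "\n".join([",".join(header)] + [",".join(f'"{c}"' for c in r) for r in rows])
    return _md_table(header, rows)


def render_subgroup_table(bundle: dict, fmt: str = "md") -> str:
    """Stratified bias table: one row per (condition, equation) pair."""
    rows = []
    for r in bundle["subgroups"]:
        bw, bo = r["bias_with"], r["bias_without"]
        rows.append(
            [
                r["condition"],
                r["equation"],
                f"{bw['median_bias']:.1f} ({bw['ci_low']:.1f}; {bw['ci_high']:.1f}) [n={bw['n']}]",
                f"{bo['median_bias']:.1f} ({bo['ci_low']:.1f}; {bo['ci_high']:.1f}) [n={bo['n']}]",
                f"{r['p_value']:.2g}",
                "yes" if r["eligible"] else "no (small stratum)",
            ]
        )
    header = ["condition", "equation", "bias with (95% CI)", "bias without (95% CI)", "p (rank-sum)", "eligible"]
    if fmt == "csv":
        return "\n".join([",".join(header)] + [",".join(f'"{c}"' for c in r) for r in rows])
    return _md_table(header, rows)


def prediction_interval_frame(bundle: dict) -> pd.DataFrame:
    """Numeric prediction-interval export: one row per (equation, threshold, level)."""
    recs = []
    for label, entry in bundle["prediction_intervals"].items():
        for t in entry["thresholds"]:
            for lvl, pred in t["percentile_predictions"].items():
                sc = t["stage_crossing"] or {}
                recs.append(
                    {
                        "equation": label,
                        "threshold": t["threshold"],
                        "level": float(lvl),
                        "predicted_mgfr": pred,
                        "width_95": t["width_95"],
                        "width_80": t["width_80"],
                        "width_50": t["width_50"],
                        "crosses_lower": sc.get("crosses_lower"),
                        "crosses_upper": sc.get("crosses_upper"),
                    }
                )
    return pd.DataFrame.from_records(recs)
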