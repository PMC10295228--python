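"""GFR-estimating equations, body-surface-area indexing, and KDIGO staging.

Implements the race-free 2021 CKD-EPI equations (creatinine and
creatinine-cystatin C), the Dubois body-surface-area formula used to
normalize a raw clearance to 1.73 m², and the KDIGO G-stage classification
of a GFR value.

The CKD-EPI equations are sex-specific piecewise power laws of the form

    eGFR = level * min(m/k, 1)^a * max(m/k, 1)^b * age_base^age * [fem]

for each marker m with breakpoint k; the coefficient sets are shipped as a
versioned JSON document (``data/ckd_epi_2021.json``) so they can be audited
and so further equations are pluggable without code changes.

All evaluators accept scalars or numpy arrays and are vectorized.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence, Union

import numpy as np

logger = logging.getLogger("egfrval")

__all__ = [
    "Subject",
    "EquationSpec",
    "bsa_dubois",
    "normalize_gfr",
    "ckd_epi_2021_cr",
    "ckd_epi_2021_crcys",
    "evaluate_equation",
    "load_equation_specs",
    "ckd_stage",
    "CKD_STAGE_CUTOFFS",
    "UMOL_PER_MGDL_CREATININE",
]

#: KDIGO G-stage lower bounds (mL/min/1.73 m²), highest stage first.
CKD_STAGE_CUTOFFS = ((90.0, "G1"), (60.0, "G2"), (45.0, "G3a"), (30.0, "G3b"), (15.0, "G4"), (0.0, "G5"))

#: Conversion factor for creatinine µmol/L -> mg/dL (divide by this).
UMOL_PER_MGDL_CREATININE = 88.4

_SEXES = ("female", "male")


class DomainError(ValueError):
    """An input lies outside the mathematical domain of an operation."""


class MissingInputError(ValueError):
    """A required equation input is absent."""


@dataclass(frozen=True)
class Subject:
    """One subject's demographics and serum markers.

    Units are fixed: age in years, creatinine (``scr``) in mg/dL, cystatin C
    (``scys``) in mg/L, height in cm, weight in kg.  Construct with
    ``scr_umol_per_l=True`` opted in at evaluation time for µmol/L input.
    """

    age: float
    sex: str
    scr: Optional[float] = None
    scys: Optional[float] = None
    height: Optional[float] = None
    weight: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if self.age is None or self.age <= 0:
            raise DomainError("age must be > 0")
        if self.age < 18:
            # adult equations; the study cohort was >= 18 years old
            logger.warning("W-AGE-UNDER18: age %.1f is below 18; adult equations applied", self.age)
        for name in ("scr", "scys", "height", "weight"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise DomainError(f"{name} must be > 0, got {v}")


@dataclass(frozen=True)
class EquationSpec:
    """A named eGFR equation given by piecewise power-law coefficients.

    ``alpha`` and ``kappa`` are per-sex mappings; the max-branch exponent(s)
    apply above the marker breakpoint.  ``cys_breakpoint`` and the cystatin
    exponents are present only for the two-marker equation.
    """

    name: str
    inputs: tuple[str, ...]
    level: float
    kappa: Mapping[str, float]
    alpha: Mapping[str, float]
    scr_max_exponent: float
    age_base: float
    female_multiplier: float
    cys_breakpoint: Optional[float] = None
    cys_min_exponent: Optional[float] = None
    cys_max_exponent: Optional[float] = None

    @property
    def uses_cystatin(self) -> bool:
        return self.cys_breakpoint is not None


def load_equation_specs() -> dict[str, EquationSpec]:
    """Load the shipped coefficient document into :class:`EquationSpec` objects."""
    text = resources.files("egfrval.data").joinpath("ckd_epi_2021.json").read_text()
    doc = json.loads(text)
    specs = {}
    for name, c in doc["equations"].items():
        specs[name] = EquationSpec(
            name=name,
            inputs=tuple(c["inputs"]),
            level=c["level"],
            kappa=c["kappa"],
            alpha=c["alpha"],
            scr_max_exponent=c["scr_max_exponent"],
            age_base=c["age_base"],
            female_multiplier=c["female_multiplier"],
            cys_breakpoint=c.get("cys_breakpoint"),
            cys_min_exponent=c.get("cys_min_exponent"),
            cys_max_exponent=c.get("cys_max_exponent"),
        )
    return specs


_SPECS = load_equation_specs()


def get_equation_spec(name: str) -> EquationSpec:
    try:
        return _SPECS[name]
    except KeyError:
        raise KeyError(f"unknown equation {name!r}; shipped: {sorted(_SPECS)}") from None


def bsa_dubois(height: Union[float, np.ndarray], weight: Union[float, np.ndarray]):
    """Dubois body surface area, m²: ``0.007184 * height^0.725 * weight^0.425``.

    ``height`` in cm, ``weight`` in kg; both strictly positive.
    """
    height = np.asarray(height, dtype=float)
    weight = np.asarray(weight, dtype=float)
    if np.any(~np.isnan(height) & (height <= 0)):
        raise DomainError("height must be > 0 cm")
    if np.any(~np.isnan(weight) & (weight <= 0)):
        raise DomainError("weight must be > 0 kg")
    out = 0.007184 * height**0.725 * weight**0.425
    return float(out) if out.ndim == 0 else out


def normalize_gfr(raw_clearance, bsa):
    """Index a raw clearance (mL/min) to 1.73 m²: ``raw * 1.73 / bsa``."""
    raw_clearance = np.asarray(raw_clearance, dtype=float)
    bsa = np.asarray(bsa, dtype=float)
    if np.any(~np.isnan(raw_clearance) & (raw_clearance < 0)):
        raise DomainError("raw_clearance must be >= 0 mL/min")
    if np.any(~np.isnan(bsa) & (bsa <= 0)):
        raise DomainError("bsa must be > 0 m²")
    out = raw_clearance * 1.73 / bsa
    return float(out) if out.ndim == 0 else out


def _sex_param(param: Mapping[str, float], female: np.ndarray) -> np.ndarray:
    return np.where(female, param["female"], param["male"])


def _as_female_mask(sex) -> np.ndarray:
    sex = np.asarray(sex)
    if sex.dtype.kind == "O":
        sex = sex.astype(str)
    if sex.dtype.kind in "US":
        bad = ~np.isin(sex, _SEXES)
        if np.any(bad):
            raise MissingInputError(f"sex must be 'female' or 'male'; got {np.unique(sex[bad])}")
        return sex == "female"
    return sex.astype(bool)


def _check_positive(name: str, value: np.ndarray) -> None:
    if np.any(np.isnan(value)):
        raise MissingInputError(f"missing required input: {name}")
    if np.any(value <= 0):
        raise DomainError(f"{name} must be strictly positive")


def evaluate_equation(
    spec: Union[str, EquationSpec],
    *,
    scr,
    age,
    sex,
    scys=None,
    scr_umol_per_l: bool = False,
):
    """Evaluate a piecewise power-law eGFR equation (vectorized).

    Parameters
    ----------
    spec
        Equation name (e.g. ``"ckd_epi_2021_cr"``) or an :class:`EquationSpec`.
    scr
        Serum creatinine, mg/dL (or µmol/L with ``scr_umol_per_l=True``).
    age
        Age in years.
    sex
        ``"female"``/``"male"`` (scalar or array), or a boolean female mask.
    scys
        Serum cystatin C, mg/L; required by the two-marker equation.

    Returns
    -------
    eGFR in mL/min/1.73 m², same shape as the broadcast inputs.
    """
    if isinstance(spec, str):
        spec = get_equation_spec(spec)
    if scr is None or age is None or sex is None:
        missing = [n for n, v in (("scr", scr), ("age", age), ("sex", sex)) if v is None]
        raise MissingInputError(f"missing required inputs: {missing}")
    scr = np.asarray(scr, dtype=float)
    if scr_umol_per_l:
        scr = scr / UMOL_PER_MGDL_CREATININE
    age = np.asarray(age, dtype=float)
    female = _as_female_mask(sex)
    _check_positive("scr", scr)
    _check_positive("age", age)
    if np.any(age < 18):
        logger.warning("W-AGE-UNDER18: ages below 18 passed to an adult equation")

    kappa = _sex_param(spec.kappa, female)
    alpha = _sex_param(spec.alpha, female)
    r = scr / kappa
    out = (
        spec.level
        * np.minimum(r, 1.0) ** alpha
        * np.maximum(r, 1.0) ** spec.scr_max_exponent
        * spec.age_base**age
        * np.where(female, spec.female_multiplier, 1.0)
    )
    if spec.uses_cystatin:
        if scys is None:
            raise MissingInputError("cystatin required for this equation (scys is missing)")
        scys = np.asarray(scys, dtype=float)
        _check_positive("scys", scys)
        c = scys / spec.cys_breakpoint
        out = out * np.minimum(c, 1.0) ** spec.cys_min_exponent * np.maximum(c, 1.0) ** spec.cys_max_exponent
    return float(out) if out.ndim == 0 else out


def ckd_epi_2021_cr(subject: Optional[Subject] = None, *, scr=None, age=None, sex=None, **kw):
    """2021 CKD-EPI creatinine eGFR (mL/min/1.73 m²).

    Pass a :class:`Subject`, or keyword arrays ``scr``, ``age``, ``sex``.
    """
    if subject is not None:
        scr, age, sex = subject.scr, subject.age, subject.sex
    return evaluate_equation("ckd_epi_2021_cr", scr=scr, age=age, sex=sex, **kw)


def ckd_epi_2021_crcys(subject: Optional[Subject] = None, *, scr=None, scys=None, age=None, sex=None, **kw):
    """2021 CKD-EPI creatinine-cystatin C eGFR (mL/min/1.73 m²)."""
    if subject is not None:
        scr, scys, age, sex = subject.scr, subject.scys, subject.age, subject.sex
    return evaluate_equation("ckd_epi_2021_crcys", scr=scr, scys=scys, age=age, sex=sex, **kw)


def ckd_stage(gfr):
    """KDIGO G stage for a GFR value (mL/min/1.73 m²).

    Intervals are lower-bound inclusive: G1 >= 90, G2 [60, 90), G3a [45, 60),
    G3b [30, 45), G4 [15, 30), G5 < 15.
    """
    arr = np.asarray(gfr, dtype=float)
    if np.any(arr <= 0):
        raise DomainError("GFR must be strictly positive for staging")
    stages = np.full(arr.shape, "G5", dtype=object)
    assigned = np.zeros(arr.shape, dtype=bool)
    for cutoff, label in CKD_STAGE_CUTOFFS:
        sel = ~assigned & (arr >= cutoff)
        stages[sel] = label
        assigned |= sel
    if arr.ndim == 0:
        return str(stages[()])
    return stages.astype(str)
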