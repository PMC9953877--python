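"""CT body-composition, metabolic, inflammatory, and frailty indices.

Everything here works from already-measured quantities: adipose and muscle
cross-sectional areas on a single CT slice at L4-L5 (cm²), liver/spleen
attenuation (HU), routine labs, and five comorbidity flags.  The derived
indices are

* BMI and WHO weight category,
* VAT/SCAT and VAT/TAT adiposity ratios and the visceral-obesity call
  (VAT area >= 100 cm², VAT/SCAT >= 0.4, or VAT/TAT >= 0.285),
* whole-body adipose tissue mass (WBAT) from Lacoste's single-slice
  linear formula 0.0677 * AT_L4-L5 + 2.5177,
* the psoas-to-L4-vertebral-body index (PLVI), with central sarcopenia
  called below a 0.45 cut (the cohort lower quartile),
* liver-minus-spleen attenuation (CT_L-S) with steatosis below -20 HU,
* the neutrophil:lymphocyte ratio, the systemic immune-inflammation index
  (platelets x ANC/ALC), and the five-item modified frailty index (mFI-5),
* the four body-composition (BC) types from crossing high/normal adiposity
  with present/absent central sarcopenia.

Missing inputs propagate as NaN/None: a classification whose every
criterion is missing raises, it is never silently False.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Timepoint",
    "BCType",
    "Trajectory",
    "SubjectRecord",
    "BodyCompositionProfile",
    "ClinicalIndices",
    "ThresholdConfig",
    "InvalidMeasurementError",
    "UndefinedClassificationError",
    "SchemaError",
    "WBAT_SLOPE",
    "WBAT_INTERCEPT",
    "compute_bmi",
    "bmi_category",
    "adiposity_ratios",
    "estimate_wbat",
    "compute_plvi",
    "classify_visceral_obesity",
    "classify_sarcopenia",
    "classify_steatosis",
    "derive_quartile_cut",
    "assign_bc_type",
    "compute_clinical_indices",
    "classify_bc_trajectory",
    "profile_record",
    "score_cohort",
    "validate_cohort_table",
    "COHORT_COLUMNS",
]

# Lacoste single-slice estimate of whole-body adipose tissue mass (kg)
# from the total adipose area (cm²) on the L4-L5 slice.
WBAT_SLOPE = 0.0677
WBAT_INTERCEPT = 2.5177


class InvalidMeasurementError(ValueError):
    """A physically impossible measurement (negative area, zero height...)."""


class UndefinedClassificationError(ValueError):
    """Every criterion needed for a categorical call is missing."""


class SchemaError(ValueError):
    """Cohort table violates the documented column schema."""


class Timepoint(str, enum.Enum):
    baseline = "baseline"
    post_treatment = "post_treatment"
    month12 = "month12"


class BCType(str, enum.Enum):
    """Body-composition type from (adiposity, muscle-mass) flags.

    ``normalA_normalM`` is the reference/best-prognosis type,
    ``highA_lowM`` (high adiposity with central sarcopenia) the worst.
    """

    normalA_normalM = "normalA_normalM"
    highA_normalM = "highA_normalM"
    normalA_lowM = "normalA_lowM"
    highA_lowM = "highA_lowM"

    @property
    def n_adverse_flags(self) -> int:
        return {"normalA_normalM": 0, "highA_normalM": 1,
                "normalA_lowM": 1, "highA_lowM": 2}[self.value]


class Trajectory(str, enum.Enum):
    improved = "improved"
    stable = "stable"
    worsened = "worsened"


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass
class SubjectRecord:
    """One subject at one timepoint: anthropometrics, CT areas, labs, flags.

    Any field may be None (missing); derived quantities needing it are then
    undefined, never zero.
    """

    subject_id: str
    timepoint: Timepoint = Timepoint.baseline
    age: Optional[float] = None              # years
    height: Optional[float] = None           # cm
    weight: Optional[float] = None           # kg
    vat_area: Optional[float] = None         # cm², visceral adipose at L4-L5
    scat_area: Optional[float] = None        # cm², subcutaneous adipose
    psoas_left_area: Optional[float] = None  # cm²
    psoas_right_area: Optional[float] = None  # cm²
    l4_body_area: Optional[float] = None     # cm², vertebral body
    liver_hu: Optional[float] = None
    spleen_hu: Optional[float] = None
    anc: Optional[float] = None              # cells/µL
    alc: Optional[float] = None              # cells/µL
    platelets: Optional[float] = None        # count/µL
    ldh: Optional[float] = None              # U/L
    albumin: Optional[float] = None          # g/dL
    cholesterol: Optional[float] = None      # mg/dL
    hypertension: Optional[bool] = None
    diabetes: Optional[bool] = None
    chf: Optional[bool] = None
    copd: Optional[bool] = None
    non_independent_status: Optional[bool] = None
    stage: Optional[str] = None              # III | IV
    surgery_type: Optional[str] = None       # upfront | interval | none
    residual: Optional[str] = None           # microscopic | macroscopic
    response: Optional[str] = None           # complete | partial_stable | progressive
    statin_metformin_use: Optional[bool] = None

    COMORBIDITY_FLAGS = (
        "hypertension", "diabetes", "chf", "copd", "non_independent_status",
    )

    def __post_init__(self) -> None:
        for name in ("vat_area", "scat_area", "psoas_left_area",
                     "psoas_right_area", "l4_body_area"):
            v = getattr(self, name)
            if not _is_missing(v) and v < 0:
                raise InvalidMeasurementError(f"{name} must be >= 0, got {v}")
        if not _is_missing(self.height) and self.height <= 0:
            raise InvalidMeasurementError(f"height must be > 0, got {self.height}")
        for name in ("anc", "alc", "platelets"):
            v = getattr(self, name)
            if not _is_missing(v) and v <= 0:
                raise InvalidMeasurementError(f"{name} must be > 0, got {v}")


@dataclass
class ThresholdConfig:
    """Every cut-off used by the categorical calls, with its inclusivity.

    Defaults are the published working cuts: visceral obesity by
    VAT >= 100 cm², VAT/SCAT >= 0.4 or VAT/TAT >= 0.285 (inclusive);
    central sarcopenia PLVI < 0.45 and steatosis CT_L-S < -20 (strict);
    WHO BMI cuts 25/30.  ``plvi_mode`` selects the PLVI numerator
    convention (bilateral psoas sum, or the single-side mean).
    """

    vat_area_cut: float = 100.0      # cm²
    vat_scat_cut: float = 0.4
    vat_tat_cut: float = 0.285
    plvi_cut: float = 0.45
    ct_ls_cut: float = -20.0         # HU
    bmi_overweight_cut: float = 25.0  # kg/m²
    bmi_obese_cut: float = 30.0
    wbat_high_rule: str = "cohort_median"   # or "fixed_kg"
    wbat_fixed_cut: Optional[float] = None  # kg, used when rule == fixed_kg
    # adiposity rule for BC typing: "vat_scat" uses the disjunctive
    # visceral-obesity call; "wbat" uses the WBAT threshold
    adiposity_rule: str = "visceral_obesity"  # or "wbat"
    # inclusivities (config-exposed; defaults follow the published wording)
    obesity_cuts_inclusive: bool = True   # >= for the three obesity criteria
    sarcopenia_cut_inclusive: bool = False  # strict <
    steatosis_cut_inclusive: bool = False   # strict <
    plvi_mode: str = "bilateral_sum"  # or "single_side_mean"
    quantile_method: str = "linear"   # numpy quantile method for cohort cuts

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and not math.isfinite(v):
                raise ValueError(f"{f.name} must be finite")
        if self.bmi_obese_cut <= self.bmi_overweight_cut:
            raise ValueError("obese cut must exceed overweight cut")
        if self.wbat_high_rule not in ("cohort_median", "fixed_kg"):
            raise ValueError(f"unknown wbat_high_rule {self.wbat_high_rule!r}")
        if self.plvi_mode not in ("bilateral_sum", "single_side_mean"):
            raise ValueError(f"unknown plvi_mode {self.plvi_mode!r}")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass
class BodyCompositionProfile:
    """Derived body-composition indices plus the categorical calls."""

    subject_id: str
    timepoint: Timepoint
    bmi: float = math.nan                 # kg/m²
    bmi_category: Optional[str] = None    # normal | overweight | obese
    at_l4l5: float = math.nan             # cm², VAT + SCAT
    vat_scat: float = math.nan
    vat_tat: float = math.nan
    wbat_kg: float = math.nan
    plvi: float = math.nan
    ct_ls: float = math.nan               # HU, liver - spleen
    visceral_obese: Optional[bool] = None
    high_adiposity: Optional[bool] = None
    sarcopenic: Optional[bool] = None
    steatosis: Optional[bool] = None
    bc_type: Optional[BCType] = None


@dataclass
class ClinicalIndices:
    """Inflammation and frailty indices from labs and comorbidity flags."""

    nlr: float = math.nan       # ANC:ALC
    siii: float = math.nan      # platelets x ANC/ALC
    mfi5: Optional[int] = None  # 0-5
    mfi5_high_risk: Optional[bool] = None


# ---------------------------------------------------------------------------
# scalar index computations
# ---------------------------------------------------------------------------

def compute_bmi(weight: float, height: float) -> float:
    """Body mass index, kg/m², from weight (kg) and height (cm)."""
    if _is_missing(weight) or _is_missing(height):
        return math.nan
    if weight <= 0 or height <= 0:
        raise InvalidMeasurementError(
            f"weight and height must be positive (got {weight}, {height})")
    return weight / (height / 100.0) ** 2


def bmi_category(bmi: float, cfg: ThresholdConfig | None = None) -> Optional[str]:
    cfg = cfg or ThresholdConfig()
    if _is_missing(bmi):
        return None
    if bmi >= cfg.bmi_obese_cut:
        return "obese"
    if bmi >= cfg.bmi_overweight_cut:
        return "overweight"
    return "normal"


def adiposity_ratios(vat_area: float, scat_area: float) -> tuple[float, float]:
    """(VAT/SCAT, VAT/TAT) with TAT = VAT + SCAT.

    VAT/SCAT is NaN when SCAT is zero; VAT/TAT is still defined as long as
    the total adipose area is positive.
    """
    if _is_missing(vat_area) or _is_missing(scat_area):
        return math.nan, math.nan
    if vat_area < 0 or scat_area < 0:
        raise InvalidMeasurementError("areas must be >= 0")
    vat_scat = vat_area / scat_area if scat_area > 0 else math.nan
    total = vat_area + scat_area
    vat_tat = vat_area / total if total > 0 else math.nan
    return vat_scat, vat_tat


def estimate_wbat(at_l4l5: float) -> float:
    """Whole-body adipose tissue mass (kg) from total L4-L5 adipose area (cm²)."""
    if _is_missing(at_l4l5):
        return math.nan
    if at_l4l5 < 0:
        raise InvalidMeasurementError(f"adipose area must be >= 0, got {at_l4l5}")
    return WBAT_SLOPE * at_l4l5 + WBAT_INTERCEPT


def compute_plvi(psoas_left: float, psoas_right: float, l4_body_area: float,
                 mode: str = "bilateral_sum") -> float:
    """Psoas-to-L4-vertebral-body index.

    Default numerator is the bilateral psoas sum; ``single_side_mean``
    divides that sum by two.
    """
    if _is_missing(psoas_left) or _is_missing(psoas_right) or _is_missing(l4_body_area):
        return math.nan
    if l4_body_area <= 0:
        raise InvalidMeasurementError(
            f"l4_body_area must be > 0, got {l4_body_area}")
    if psoas_left < 0 or psoas_right < 0:
        raise InvalidMeasurementError("psoas areas must be >= 0")
    total = psoas_left + psoas_right
    if mode == "single_side_mean":
        total /= 2.0
    elif mode != "bilateral_sum":
        raise ValueError(f"unknown PLVI mode {mode!r}")
    return total / l4_body_area


# ---------------------------------------------------------------------------
# categorical calls
# ---------------------------------------------------------------------------

def _meets(value: float, cut: float, inclusive: bool, direction: str) -> bool:
    if direction == "ge":
        return value >= cut if inclusive else value > cut
    return value <= cut if inclusive else value < cut


def classify_visceral_obesity(vat_area: float, vat_scat: float, vat_tat: float,
                              cfg: ThresholdConfig | None = None) -> bool:
    """Disjunctive visceral-obesity rule; missing criteria are skipped.

    True iff ANY evaluable criterion meets its cut.  All three missing is
    an error, never a silent False.
    """
    cfg = cfg or ThresholdConfig()
    crit = [(vat_area, cfg.vat_area_cut), (vat_scat, cfg.vat_scat_cut),
            (vat_tat, cfg.vat_tat_cut)]
    evaluable = [(v, c) for v, c in crit if not _is_missing(v)]
    if not evaluable:
        raise UndefinedClassificationError(
            "all visceral-obesity criteria are missing")
    return any(_meets(v, c, cfg.obesity_cuts_inclusive, "ge")
               for v, c in evaluable)


def classify_sarcopenia(plvi: float, cfg: ThresholdConfig | None = None) -> bool:
    """Central sarcopenia: PLVI below the cut (strict by default)."""
    cfg = cfg or ThresholdConfig()
    if _is_missing(plvi):
        raise UndefinedClassificationError("PLVI is missing")
    return _meets(plvi, cfg.plvi_cut, cfg.sarcopenia_cut_inclusive, "le")


def classify_steatosis(liver_hu: float, spleen_hu: float,
                       cfg: ThresholdConfig | None = None) -> tuple[float, bool]:
    """(CT_L-S, steatosis): liver minus spleen HU, steatosis below the cut."""
    cfg = cfg or ThresholdConfig()
    if _is_missing(liver_hu) or _is_missing(spleen_hu):
        raise UndefinedClassificationError("liver or spleen HU is missing")
    ct_ls = liver_hu - spleen_hu
    return ct_ls, _meets(ct_ls, cfg.ct_ls_cut, cfg.steatosis_cut_inclusive, "le")


def derive_quartile_cut(values: Sequence[float], quartile: float = 0.25,
                        method: str = "linear") -> float:
    """Empirical quantile boundary for a cohort-specific cut.

    The published PLVI cut is the lowest quartile of the pooled cohort;
    this recomputes such a cut on any sample (linear-interpolation
    quantile by default).
    """
    arr = np.asarray([v for v in values if not _is_missing(v)], dtype=float)
    if arr.size < 4:
        raise ValueError(
            f"need >= 4 finite values to derive a quartile cut, got {arr.size}")
    if not 0 < quartile < 1:
        raise ValueError("quartile must be in (0, 1)")
    return float(np.quantile(arr, quartile, method=method))


_BC_TABLE = {
    (False, False): BCType.normalA_normalM,
    (True, False): BCType.highA_normalM,
    (False, True): BCType.normalA_lowM,
    (True, True): BCType.highA_lowM,
}


def assign_bc_type(high_adiposity: Optional[bool],
                   sarcopenic: Optional[bool]) -> BCType:
    """One of the four BC types from the 2x2 (adiposity, sarcopenia) flags."""
    if high_adiposity is None or sarcopenic is None:
        raise UndefinedClassificationError(
            "both adiposity and sarcopenia flags are required")
    return _BC_TABLE[(bool(high_adiposity), bool(sarcopenic))]


def compute_clinical_indices(record: SubjectRecord) -> ClinicalIndices:
    """NLR, SIII (platelets x ANC/ALC), and mFI-5 with its >= 1 risk flag."""
    out = ClinicalIndices()
    if not (_is_missing(record.anc) or _is_missing(record.alc)) and record.alc > 0:
        out.nlr = record.anc / record.alc
        if not _is_missing(record.platelets):
            out.siii = record.platelets * out.nlr
    flags = [getattr(record, f) for f in SubjectRecord.COMORBIDITY_FLAGS]
    if all(f is not None for f in flags):
        out.mfi5 = int(sum(bool(f) for f in flags))
        out.mfi5_high_risk = out.mfi5 >= 1
    return out


def classify_bc_trajectory(baseline: BodyCompositionProfile,
                           month12: BodyCompositionProfile) -> Trajectory:
    """Trajectory of the BC type between two timepoints of one subject.

    Improvement means strictly fewer adverse flags (closer to
    normalA_normalM) at the later timepoint; more means worsened.
    """
    if baseline.bc_type is None or month12.bc_type is None:
        raise UndefinedClassificationError("both BC types must be defined")
    if baseline.subject_id != month12.subject_id:
        raise ValueError("profiles belong to different subjects")
    before = baseline.bc_type.n_adverse_flags
    after = month12.bc_type.n_adverse_flags
    if after < before:
        return Trajectory.improved
    if after > before:
        return Trajectory.worsened
    return Trajectory.stable


# ---------------------------------------------------------------------------
# per-record and cohort-level profiling
# ---------------------------------------------------------------------------

def profile_record(record: SubjectRecord, cfg: ThresholdConfig | None = None,
                   wbat_cut: Optional[float] = None) -> BodyCompositionProfile:
    """Full body-composition profile for one record.

    ``wbat_cut`` (kg) is required for WBAT-based high-adiposity typing when
    ``cfg.adiposity_rule == "wbat"``; with the default cohort-median rule it
    comes from :func:`score_cohort`.
    """
    cfg = cfg or ThresholdConfig()
    p = BodyCompositionProfile(record.subject_id, record.timepoint)
    try:
        p.bmi = compute_bmi(record.weight, record.height)
    except InvalidMeasurementError:
        p.bmi = math.nan
    p.bmi_category = bmi_category(p.bmi, cfg)
    p.vat_scat, p.vat_tat = adiposity_ratios(record.vat_area, record.scat_area)
    if not (_is_missing(record.vat_area) or _is_missing(record.scat_area)):
        p.at_l4l5 = record.vat_area + record.scat_area
        p.wbat_kg = estimate_wbat(p.at_l4l5)
    p.plvi = compute_plvi(record.psoas_left_area, record.psoas_right_area,
                          record.l4_body_area, mode=cfg.plvi_mode)
    try:
        p.visceral_obese = classify_visceral_obesity(
            record.vat_area, p.vat_scat, p.vat_tat, cfg)
    except UndefinedClassificationError:
        p.visceral_obese = None
    if cfg.adiposity_rule == "wbat":
        if wbat_cut is not None and not _is_missing(p.wbat_kg):
            p.high_adiposity = bool(p.wbat_kg >= wbat_cut)
    else:
        p.high_adiposity = p.visceral_obese
    try:
        p.sarcopenic = classify_sarcopenia(p.plvi, cfg)
    except UndefinedClassificationError:
        p.sarcopenic = None
    try:
        p.ct_ls, p.steatosis = classify_steatosis(
            record.liver_hu, record.spleen_hu, cfg)
    except UndefinedClassificationError:
        p.ct_ls, p.steatosis = math.nan, None
    if p.high_adiposity is not None and p.sarcopenic is not None:
        p.bc_type = assign_bc_type(p.high_adiposity, p.sarcopenic)
    return p


#: documented column dictionary for the cohort table (name -> dtype kind)
COHORT_COLUMNS = {
    "subject_id": "str", "timepoint": "str", "age": "float",
    "height": "float", "weight": "float", "vat_area": "float",
    "scat_area": "float", "psoas_left_area": "float",
    "psoas_right_area": "float", "l4_body_area": "float",
    "liver_hu": "float", "spleen_hu": "float", "anc": "float",
    "alc": "float", "platelets": "float", "ldh": "float",
    "albumin": "float", "cholesterol": "float", "hypertension": "bool",
    "diabetes": "bool", "chf": "bool", "copd": "bool",
    "non_independent_status": "bool", "stage": "str", "surgery_type": "str",
    "residual": "str", "response": "str", "statin_metformin_use": "bool",
}

_ENUM_COLUMNS = {
    "timepoint": {t.value for t in Timepoint},
    "stage": {"III", "IV"},
    "surgery_type": {"upfront", "interval", "none"},
    "residual": {"microscopic", "macroscopic"},
    "response": {"complete", "partial_stable", "progressive"},
}

_NONNEG_COLUMNS = ("vat_area", "scat_area", "psoas_left_area",
                   "psoas_right_area", "l4_body_area")
_POSITIVE_COLUMNS = ("height", "anc", "alc", "platelets")


def validate_cohort_table(df: pd.DataFrame) -> list[str]:
    """Validate a cohort table against the documented schema.

    Returns a list of human-readable, line-numbered error strings (empty
    when the table is valid).  Row numbers are 1-based data rows.
    """
    errors: list[str] = []
    missing_cols = [c for c in ("subject_id", "timepoint") if c not in df.columns]
    for c in missing_cols:
        errors.append(f"missing required column {c!r}")
    if missing_cols:
        return errors
    unknown = [c for c in df.columns
               if c not in COHORT_COLUMNS and not c.startswith(("true_", "time_", "event_"))]
    for c in unknown:
        errors.append(f"unknown column {c!r}")
    for col, allowed in _ENUM_COLUMNS.items():
        if col not in df.columns:
            continue
        vals = df[col].dropna()
        bad = vals[~vals.isin(allowed)]
        for idx, v in bad.items():
            errors.append(
                f"row {idx + 1}: {col}={v!r} not in {sorted(allowed)}")
    for col in _NONNEG_COLUMNS:
        if col not in df.columns:
            continue
        num = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[num < 0]
        for idx in bad:
            errors.append(f"row {idx + 1}: {col} must be >= 0, got {df[col][idx]}")
    for col in _POSITIVE_COLUMNS:
        if col not in df.columns:
            continue
        num = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[num <= 0]
        for idx in bad:
            errors.append(f"row {idx + 1}: {col} must be > 0, got {df[col][idx]}")
    return errors


def _record_from_row(row: pd.Series) -> SubjectRecord:
    kwargs = {}
    for name in COHORT_COLUMNS:
        if name not in row.index:
            continue
        v = row[name]
        if pd.isna(v):
            v = None
        elif COHORT_COLUMNS[name] == "bool" and not isinstance(v, bool):
            v = bool(int(v)) if not isinstance(v, str) else v.lower() in ("true", "1", "yes")
        elif COHORT_COLUMNS[name] == "float":
            v = float(v)
        kwargs[name] = v
    kwargs["timepoint"] = Timepoint(kwargs.get("timepoint") or "baseline")
    return SubjectRecord(**kwargs)


def score_cohort(df: pd.DataFrame, cfg: ThresholdConfig | None = None,
                 validate: bool = True) -> pd.DataFrame:
    """Profile every row of a cohort table.

    Returns a tidy frame (one row per subject-timepoint) with all derived
    indices and categorical calls.  When the WBAT high-adiposity rule is
    ``cohort_median`` the cut is the baseline-timepoint median WBAT.
    """
    cfg = cfg or ThresholdConfig()
    if validate:
        errors = validate_cohort_table(df)
        if errors:
            raise SchemaError("; ".join(errors[:20]))
    records = [_record_from_row(row) for _, row in df.iterrows()]

    wbat_cut = cfg.wbat_fixed_cut
    if cfg.adiposity_rule == "wbat" and cfg.wbat_high_rule == "cohort_median":
        base_wbat = [estimate_wbat(r.vat_area + r.scat_area)
                     for r in records
                     if r.timepoint == Timepoint.baseline
                     and not (_is_missing(r.vat_area) or _is_missing(r.scat_area))]
        wbat_cut = float(np.median(base_wbat)) if base_wbat else None

    rows = []
    for rec in records:
        p = profile_record(rec, cfg, wbat_cut=wbat_cut)
        ci = compute_clinical_indices(rec)
        rows.append({
            "subject_id": p.subject_id, "timepoint": p.timepoint.value,
            "bmi": p.bmi, "bmi_category": p.bmi_category,
            "at_l4l5": p.at_l4l5, "vat_scat": p.vat_scat,
            "vat_tat": p.vat_tat, "wbat_kg": p.wbat_kg, "plvi": p.plvi,
            "ct_ls": p.ct_ls, "visceral_obese": p.visceral_obese,
            "high_adiposity": p.high_adiposity, "sarcopenic": p.sarcopenic,
            "steatosis": p.steatosis,
            "bc_type": p.bc_type.value if p.bc_type else None,
            "nlr": ci.nlr, "siii": ci.siii, "mfi5": ci.mfi5,
            "mfi5_high_risk": ci.mfi5_high_risk,
        })
    return pd.DataFrame(rows)
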