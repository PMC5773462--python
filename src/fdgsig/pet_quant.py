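"""FDG-PET quantification metrics and uptake-value screening.

Implements the standard VOI-level quantification parameters used to
characterise tumor glucose uptake on FDG-PET/CT:

* SUL — SUV normalised to lean body mass (Janmahasatian formula),
* SUVglu — SUV rescaled by basal blood glucose relative to 100 mg/dl,
* MTV / TLG — metabolic tumor volume and total lesion glycolysis,
* T/B — tumor-to-background ratio from two matched circular ROIs,

together with the base-2 log transform used to bring the SUV outcome
close to normality, Tukey-style IQR outlier fences, and the
"influential observation" rule (a value below the reference minimum
that is nevertheless inside the low fence).

All SUV inputs refer to SUVmean35 — the mean SUV inside a 3D isocontour
at 35% of the maximum pixel value — unless stated otherwise. No partial
volume correction is applied anywhere in this module.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "Sex",
    "ObservationClass",
    "PatientCovariates",
    "VOIStats",
    "PETRecord",
    "OutlierFences",
    "compute_lbm",
    "compute_sul",
    "compute_suvglu",
    "compute_mtv_tlg",
    "compute_tb_index",
    "log2_transform",
    "outlier_fences",
    "classify_observation",
    "screen_distribution",
    "build_record",
    "quantify_cohort",
    "cohort_summary",
]


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class ObservationClass(str, enum.Enum):
    LOW_OUTLIER = "low_outlier"
    HIGH_OUTLIER = "high_outlier"
    INFLUENTIAL = "influential"
    IN_RANGE = "in_range"


@dataclass(frozen=True)
class PatientCovariates:
    """Anthropometric and metabolic covariates of one patient.

    weight in kg, height in m, basal glucose in mg/dl. ``injected_dose``
    (MBq) is bookkeeping only and enters no formula.
    """

    patient_id: str
    sex: Sex
    weight: float
    height: float
    basal_glucose: float
    injected_dose: Optional[float] = None

    def __post_init__(self) -> None:
        if self.weight <= 0 or self.height <= 0:
            raise ValueError(
                f"patient {self.patient_id}: weight and height must be positive, "
                f"got weight={self.weight}, height={self.height}"
            )
        if self.basal_glucose <= 0:
            raise ValueError(
                f"patient {self.patient_id}: basal glucose must be positive"
            )
        if not isinstance(self.sex, Sex):
            object.__setattr__(self, "sex", Sex(self.sex))

    @property
    def bmi(self) -> float:
        """Body mass index, weight / height^2 (kg/m^2)."""
        return self.weight / self.height**2


@dataclass(frozen=True)
class VOIStats:
    """VOI-level PET statistics for one lesion.

    ``suv_mean35`` is the mean SUV inside the 35%-of-maximum isocontour;
    ``voi_volume_cm3`` may be missing (NaN) — volume-derived metrics then
    propagate as missing rather than raising.
    """

    suv_max: float
    suv_mean35: float
    voi_volume_cm3: float = math.nan
    tumor_roi_mean: float = math.nan
    background_roi_mean: float = math.nan

    def __post_init__(self) -> None:
        if self.suv_mean35 <= 0 or self.suv_max <= 0:
            raise ValueError("SUV values must be positive")
        if self.suv_mean35 > self.suv_max + 1e-12:
            raise ValueError(
                f"suv_mean35 ({self.suv_mean35}) cannot exceed suv_max ({self.suv_max})"
            )


@dataclass(frozen=True)
class PETRecord:
    """One patient's covariates, VOI statistics and derived metrics."""

    covariates: PatientCovariates
    voi: VOIStats
    lbm: float
    sul: float
    suv_glu: float
    mtv: float
    tlg: float
    tb_index: float
    log2_suv: float


@dataclass(frozen=True)
class OutlierFences:
    """IQR fences of a reference SUV sample.

    low_fence = P1 - 1.5 (P3 - P1), high_fence = P3 + 1.5 (P3 - P1),
    where P1/P3 are the 25th/75th percentiles. ``reference_min`` is kept
    so values below the observed minimum but inside the low fence can be
    flagged as influential observations.
    """

    p1: float
    p3: float
    low_fence: float
    high_fence: float
    reference_min: float

    def __post_init__(self) -> None:
        if self.p3 < self.p1:
            raise ValueError("p3 must be >= p1")


def compute_lbm(cov: PatientCovariates) -> float:
    """Lean body mass (kg) by the Janmahasatian sex-specific formula.

    male:   9270 W / (6680 + 216 BMI)
    female: 9270 W / (8780 + 244 BMI)
    """
    bmi = cov.bmi
    if cov.sex is Sex.MALE:
        return 9270.0 * cov.weight / (6680.0 + 216.0 * bmi)
    if cov.sex is Sex.FEMALE:
        return 9270.0 * cov.weight / (8780.0 + 244.0 * bmi)
    raise ValueError(f"unknown sex: {cov.sex!r}")


def compute_sul(suv_mean35: float, lbm: float, weight: float) -> float:
    """SUV normalised to lean body mass: SUL = LBM * SUVmean35 / weight."""
    if suv_mean35 <= 0 or lbm <= 0 or weight <= 0:
        raise ValueError("SUL inputs must all be positive")
    return lbm * suv_mean35 / weight


def compute_suvglu(suv_mean35: float, basal_glucose: float) -> float:
    """Glucose-corrected SUV: SUVglu = SUVmean35 * glucose / 100 mg/dl."""
    if suv_mean35 <= 0 or basal_glucose <= 0:
        raise ValueError("SUVglu inputs must be positive")
    return suv_mean35 * basal_glucose / 100.0


def compute_mtv_tlg(voi: VOIStats) -> tuple[float, float]:
    """Metabolic tumor volume and total lesion glycolysis.

    MTV is the volume (cm^3) of the 35%-thresholded VOI; TLG = SUVmean35 * MTV.
    A missing volume yields (nan, nan) — missing markers, not errors —
    since cohorts legitimately contain patients without a volume estimate.
    """
    if voi.voi_volume_cm3 is None or math.isnan(voi.voi_volume_cm3):
        return math.nan, math.nan
    if voi.voi_volume_cm3 <= 0:
        raise ValueError("VOI volume must be positive when present")
    mtv = voi.voi_volume_cm3
    return mtv, voi.suv_mean35 * mtv


def compute_tb_index(tumor_roi_mean: float, background_roi_mean: float) -> float:
    """Tumor-to-background ratio of two identical circular ROI means."""
    if math.isnan(tumor_roi_mean) or math.isnan(background_roi_mean):
        return math.nan
    if background_roi_mean <= 0:
        raise ZeroDivisionError(
            "background ROI mean must be positive to form the T/B ratio"
        )
    return tumor_roi_mean / background_roi_mean


def log2_transform(values) -> np.ndarray:
    """Base-2 logarithm of a positive SUV vector (invertible by 2**x)."""
    arr = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("log2 transform requires finite positive values")
    return np.log2(arr)


def outlier_fences(
    reference: Sequence[float], *, method: str = "linear"
) -> OutlierFences:
    """IQR fences from a reference sample of SUV values.

    ``method`` is the percentile interpolation rule passed to
    :func:`numpy.percentile` (default linear interpolation between order
    statistics).
    """
    arr = np.asarray(reference, dtype=float)
    if arr.size < 4:
        raise ValueError("need at least 4 reference values to set fences")
    p1, p3 = np.percentile(arr, [25, 75], method=method)
    iqr = p3 - p1
    return OutlierFences(
        p1=float(p1),
        p3=float(p3),
        low_fence=float(p1 - 1.5 * iqr),
        high_fence=float(p3 + 1.5 * iqr),
        reference_min=float(arr.min()),
    )


def classify_observation(value: float, fences: OutlierFences) -> ObservationClass:
    """Classify a value against reference fences.

    low/high outliers use inclusive comparisons (<= low fence, >= high
    fence); "influential" is the open interval (low_fence, reference_min):
    below every training value yet not an outlier. The reference minimum
    itself is in range.
    """
    if value <= fences.low_fence:
        return ObservationClass.LOW_OUTLIER
    if value >= fences.high_fence:
        return ObservationClass.HIGH_OUTLIER
    if value < fences.reference_min:
        return ObservationClass.INFLUENTIAL
    return ObservationClass.IN_RANGE


def screen_distribution(values: Sequence[float]) -> dict:
    """Normality screen of an uptake parameter.

    Returns Shapiro-Wilk and Lilliefors (Kolmogorov-Smirnov with
    estimated parameters) p-values, the sample skewness, and a flag that
    is true when both tests have p > 0.05. A constant sample is flagged
    non-normal with a warning rather than raising.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 8:
        raise ValueError("need at least 8 values to screen a distribution")
    if np.ptp(arr) == 0:
        warnings.warn("constant sample: distribution flagged non-normal")
        return {
            "shapiro_p": 0.0,
            "ks_p": 0.0,
            "skewness": 0.0,
            "normal_flag": False,
        }
    shapiro_p = float(stats.shapiro(arr).pvalue)
    ks_p = float(lilliefors(arr, dist="norm")[1])
    return {
        "shapiro_p": shapiro_p,
        "ks_p": ks_p,
        "skewness": float(stats.skew(arr, bias=False)),
        "normal_flag": bool(shapiro_p > 0.05 and ks_p > 0.05),
    }


def build_record(cov: PatientCovariates, voi: VOIStats) -> PETRecord:
    """Assemble the full quantification record for one patient."""
    lbm = compute_lbm(cov)
    mtv, tlg = compute_mtv_tlg(voi)
    return PETRecord(
        covariates=cov,
        voi=voi,
        lbm=lbm,
        sul=compute_sul(voi.suv_mean35, lbm, cov.weight),
        suv_glu=compute_suvglu(voi.suv_mean35, cov.basal_glucose),
        mtv=mtv,
        tlg=tlg,
        tb_index=compute_tb_index(voi.tumor_roi_mean, voi.background_roi_mean),
        log2_suv=float(np.log2(voi.suv_mean35)),
    )


_CSV_COLUMNS = [
    "patient_id",
    "sex",
    "weight_kg",
    "height_m",
    "glucose_mg_dl",
    "suv_max",
    "suv_mean35",
    "voi_volume_cm3",
    "tumor_roi_mean",
    "background_roi_mean",
]


def quantify_cohort(patients: pd.DataFrame) -> pd.DataFrame:
    """Quantification table for a per-patient covariate table.

    ``patients`` follows the CSV column contract (patient_id, sex,
    weight_kg, height_m, glucose_mg_dl, suv_max, suv_mean35,
    voi_volume_cm3, tumor_roi_mean, background_roi_mean); missing
    VOI volume / ROI means may be NaN. Returns one row per patient with
    every derived metric.
    """
    missing = [c for c in _CSV_COLUMNS if c not in patients.columns]
    if missing:
        raise ValueError(f"patient table lacks columns: {missing}")
    rows = []
    for _, r in patients.iterrows():
        cov = PatientCovariates(
            patient_id=str(r["patient_id"]),
            sex=Sex(r["sex"]),
            weight=float(r["weight_kg"]),
            height=float(r["height_m"]),
            basal_glucose=float(r["glucose_mg_dl"]),
        )
        voi = VOIStats(
            suv_max=float(r["suv_max"]),
            suv_mean35=float(r["suv_mean35"]),
            voi_volume_cm3=float(r.get("voi_volume_cm3", math.nan)),
            tumor_roi_mean=float(r.get("tumor_roi_mean", math.nan)),
            background_roi_mean=float(r.get("background_roi_mean", math.nan)),
        )
        rec = build_record(cov, voi)
        rows.append(
            {
                "patient_id": cov.patient_id,
                "sex": cov.sex.value,
                "bmi": cov.bmi,
                "lbm": rec.lbm,
                "suv_max": voi.suv_max,
                "suv_mean35": voi.suv_mean35,
                "sul": rec.sul,
                "suv_glu": rec.suv_glu,
                "mtv": rec.mtv,
                "tlg": rec.tlg,
                "tb_index": rec.tb_index,
                "log2_suv": rec.log2_suv,
            }
        )
    return pd.DataFrame(rows)


def cohort_summary(table: pd.DataFrame) -> dict:
    """Mean and range per quantification metric (missing values noted)."""
    out = {"n": int(len(table))}
    for col in ["lbm", "suv_max", "suv_mean35", "sul", "suv_glu", "mtv", "tlg", "tb_index"]:
        if col not in table.columns:
            continue
        vals = table[col].astype(float)
        out[col] = {
            "mean": float(vals.mean()),
            "min": float(vals.min()),
            "max": float(vals.max()),
            "n_missing": int(vals.isna().sum()),
        }
    return out


def summary_to_json(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
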