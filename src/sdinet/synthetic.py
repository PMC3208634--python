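"""Seeded synthetic cohorts of postmenopausal osteoporosis-clinic patients.

No patient-level data accompany the study this pipeline replicates, so every
downstream stage is exercised on simulated cohorts whose marginal structure
matches the published cohort description: the distributions of the
continuous clinical measurements, the prevalences of the yes/no risk
factors, and per-patient vertebral fracture burden driven by a logistic
liability whose default coefficients are the published multivariable odds
ratios (per year since menopause 1.07, previous fragility fracture 1.28,
arterial hypertension 1.54, COPD 2.63, daily calcium 1.00, low BMD 1.06,
absence of dyslipidemia 2.21).

Fracture generation is a two-stage hurdle.  Stage one draws fractured
yes/no from ``logit P(SDI>=1) = alpha + x'beta``, so the configured odds
ratios are *exactly* the estimands of a patient-level logistic refit of the
any-fracture endpoint -- the property the calibration-recovery tests rely
on.  Stage two spreads the burden over the thirteen T4-L4 vertebrae:
conditional on being fractured, each vertebra fractures independently with
probability ``sigmoid(eta + severity_shift)`` (at least one is forced), and
each fractured vertebra draws its severity grade from a multinomial over
grades 1-3.  Severity therefore rises monotonically with the same liability
that drives fracture status, producing the long right tail of the SDI
distribution seen in the clinic population.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from . import morphometry
from ._util import substream


class CohortConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


@dataclass(frozen=True)
class TruncNormal:
    """Normal distribution clamped to [low, high]."""

    mean: float
    sd: float
    low: float
    high: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.clip(rng.normal(self.mean, self.sd, n), self.low, self.high)


# Defaults reproduce the published "all patients" column: age 68.0+/-8.5 y,
# calcium 636+/-404 mg/day, BMI median 23 (16-41); years since menopause come
# out as age minus a 50+/-4 age at menopause (median ~18, range ~1-50),
# preserving the reported age-SDI / YSM-SDI correlation structure.
DEFAULT_CONTINUOUS: dict[str, TruncNormal] = {
    "age": TruncNormal(68.0, 8.5, 45.0, 90.0),
    "age_at_menopause": TruncNormal(50.0, 4.0, 35.0, 60.0),
    "bmi": TruncNormal(23.5, 3.5, 16.0, 41.0),
    "calcium_mg_day": TruncNormal(636.0, 404.0, 0.0, 2400.0),
}

DEFAULT_PREVALENCES: dict[str, float] = {
    "current_smoking": 0.153,
    "previous_smoking": 0.102,
    "alcohol_ge_3_units": 0.333,
    "low_bmd": 0.651,
    "previous_fracture": 0.089,
    "family_hip_fracture": 0.172,
    "hypertension": 0.296,
    "dyslipidemia": 0.148,
    "gastric_disease": 0.226,
    "anxiety_depression": 0.134,
    "copd": 0.038,
    "osteoarthritis": 0.215,
    "kidney_stones": 0.046,
    "t2d": 0.038,
}

#: Log odds of the seven-covariate liability (published multivariable ORs).
DEFAULT_LIABILITY: dict[str, float] = {
    "ysm": float(np.log(1.07)),
    "previous_fracture": float(np.log(1.28)),
    "hypertension": float(np.log(1.54)),
    "copd": float(np.log(2.63)),
    "calcium_mg_day": 0.0,  # OR 1.00 per mg/day
    "low_bmd": float(np.log(1.06)),
    "dyslipidemia_absence": float(np.log(2.21)),
}

#: Intercept calibrated once so the default covariate mix yields the
#: clinic prevalence P(SDI>=1) ~ 176/372 = 0.473.
DEFAULT_BASELINE_LOG_ODDS = -2.245

#: Liability shift for per-vertebra spread; -1.8 yields P(SDI>=5) ~ 0.14
#: overall with a right tail reaching past SDI 20, as in the clinic sample.
DEFAULT_SEVERITY_SHIFT = -1.8


@dataclass
class CohortConfig:
    n_patients: int = 372
    seed: int = 0
    continuous_specs: dict[str, TruncNormal] = field(
        default_factory=lambda: dict(DEFAULT_CONTINUOUS)
    )
    binary_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    liability_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LIABILITY)
    )
    baseline_log_odds: float = DEFAULT_BASELINE_LOG_ODDS
    severity_shift: float = DEFAULT_SEVERITY_SHIFT
    grade_severity_params: tuple[float, float, float] = (0.6, 0.3, 0.1)
    missing_rate: float = 0.0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise CohortConfigError("n_patients must be >= 1")
        for name, spec in self.continuous_specs.items():
            if spec.sd <= 0:
                raise CohortConfigError(f"continuous_specs[{name!r}]: sd must be > 0")
            if spec.high <= spec.low:
                raise CohortConfigError(f"continuous_specs[{name!r}]: high must exceed low")
        for name, p in self.binary_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise CohortConfigError(f"binary_prevalences[{name!r}] must lie in [0, 1]")
        probs = np.asarray(self.grade_severity_params, dtype=float)
        if probs.shape != (3,) or probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
            raise CohortConfigError("grade_severity_params must be 3 probabilities summing to 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise CohortConfigError("missing_rate must lie in [0, 1)")
        smoke = self.binary_prevalences.get("current_smoking", 0.0) + self.binary_prevalences.get(
            "previous_smoking", 0.0
        )
        if smoke > 1.0:
            raise CohortConfigError(
                "binary_prevalences: current plus previous smoking exceed 1"
            )


@dataclass
class SyntheticCohort:
    records: pd.DataFrame
    sq_grades: np.ndarray  # (n_patients, 13) ints
    sdi: np.ndarray  # (n_patients,) ints
    truth: dict

    def write(self, outdir: str | Path, stem: str = "cohort") -> tuple[Path, Path]:
        """Write the cohort CSV plus a truth JSON sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        csv_path = outdir / f"{stem}.csv"
        table = self.records.copy()
        table["sdi"] = self.sdi
        table.to_csv(csv_path, index=False)
        truth_path = outdir / f"{stem}.truth.json"
        truth_path.write_text(json.dumps(self.truth, indent=2, sort_keys=True))
        return csv_path, truth_path


def _liability(config: CohortConfig, records: pd.DataFrame) -> np.ndarray:
    eta = np.full(len(records), config.baseline_log_odds, dtype=float)
    covariates = records.assign(
        dyslipidemia_absence=1 - records["dyslipidemia"]
    )
    for name, beta in config.liability_coefficients.items():
        if name not in covariates.columns:
            raise CohortConfigError(f"liability_coefficients: unknown covariate {name!r}")
        eta += beta * covariates[name].to_numpy(dtype=float)
    return eta


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Draw one seeded cohort.  Bit-for-bit reproducible for a fixed seed."""
    config = config or CohortConfig()
    config.validate()
    n = config.n_patients
    seed = config.seed

    records = pd.DataFrame({"patient_id": np.arange(1, n + 1)})
    for name, spec in config.continuous_specs.items():
        records[name] = spec.sample(substream(seed, f"cont:{name}"), n)
    if {"age", "age_at_menopause"} <= set(records.columns):
        records["ysm"] = np.maximum(records["age"] - records["age_at_menopause"], 1.0)

    # reproductive history: counts with the clinic medians (2 pregnancies,
    # ~3 months breast feeding with a long tail)
    rng = substream(seed, "pregnancies")
    records["pregnancies"] = np.minimum(rng.poisson(2.0, n), 8)
    rng = substream(seed, "breastfeeding")
    bf = np.where(
        rng.random(n) < 0.25,
        0.0,
        np.round(np.exp(rng.normal(np.log(4.0), 1.0, n))),
    )
    records["breastfeeding_months"] = np.clip(bf, 0, 72)

    # smoking status as one categorical draw so current/ex are exclusive
    p_cur = config.binary_prevalences.get("current_smoking", 0.0)
    p_ex = config.binary_prevalences.get("previous_smoking", 0.0)
    u = substream(seed, "smoking").random(n)
    records["current_smoking"] = (u < p_cur).astype(int)
    records["previous_smoking"] = ((u >= p_cur) & (u < p_cur + p_ex)).astype(int)

    # alcohol: heavy drinkers (>= 3 units/day) at the configured prevalence;
    # light drinkers spread below 3 units; capped at the 100 g/day
    # (12.5 units) secondary-osteoporosis exclusion bound
    p_heavy = config.binary_prevalences.get("alcohol_ge_3_units", 0.0)
    rng = substream(seed, "alcohol")
    heavy = rng.random(n) < p_heavy
    units = np.where(heavy, 3.0 + rng.exponential(1.0, n), rng.uniform(0.0, 2.99, n))
    records["alcohol_units_per_day"] = np.minimum(units, 12.5)

    for name, p in config.binary_prevalences.items():
        if name in ("current_smoking", "previous_smoking", "alcohol_ge_3_units"):
            continue
        records[name] = (substream(seed, f"bin:{name}").random(n) < p).astype(int)

    eta = _liability(config, records)
    p_any = expit(eta)
    rng = substream(seed, "fracture")
    fractured = rng.random(n) < p_any

    # spread the burden over the 13 vertebrae
    q = expit(eta + config.severity_shift)
    vert_frac = rng.random((n, morphometry.N_VERTEBRAE)) < q[:, None]
    vert_frac[~fractured] = False
    none_hit = fractured & ~vert_frac.any(axis=1)
    if none_hit.any():
        forced = rng.integers(0, morphometry.N_VERTEBRAE, none_hit.sum())
        vert_frac[np.flatnonzero(none_hit), forced] = True

    grades = np.zeros((n, morphometry.N_VERTEBRAE), dtype=int)
    draws = rng.choice([1, 2, 3], size=grades.shape, p=list(config.grade_severity_params))
    grades[vert_frac] = draws[vert_frac]
    sdi = grades.sum(axis=1)

    if config.missing_rate > 0:
        rng = substream(seed, "missingness")
        cols = [c for c in records.columns if c != "patient_id"]
        mask = rng.random((n, len(cols))) < config.missing_rate
        records[cols] = records[cols].astype(float).mask(mask)

    truth = {
        "seed": seed,
        "n_patients": n,
        "baseline_log_odds": config.baseline_log_odds,
        "severity_shift": config.severity_shift,
        "liability_coefficients": dict(config.liability_coefficients),
        "liability_odds_ratios": {
            k: float(np.exp(v)) for k, v in config.liability_coefficients.items()
        },
        "grade_severity_params": list(config.grade_severity_params),
        "binary_prevalences": dict(config.binary_prevalences),
        "continuous_specs": {k: asdict(v) for k, v in config.continuous_specs.items()},
    }
    return SyntheticCohort(records=records, sq_grades=grades, sdi=sdi, truth=truth)


# Height synthesis keeps compressions strictly inside each grade's band so
# regrading the heights always returns the input grades (round-trip
# property).  Posterior heights are shared within the column, which keeps
# the crush term (posterior vs adjacent posterior) at zero.
_BANDS = {0: (0.0, 0.19), 1: (0.205, 0.245), 2: (0.255, 0.395), 3: (0.405, 0.60)}


def generate_vertebral_heights(grades, seed: int = 0) -> pd.DataFrame:
    """Synthesize 6-point-morphometry heights consistent with 13 SQ grades."""
    g = np.asarray(grades, dtype=int)
    if g.shape != (morphometry.N_VERTEBRAE,):
        raise ValueError(f"expected {morphometry.N_VERTEBRAE} grades")
    if g.min() < 0 or g.max() > 3:
        raise ValueError("SQ grades must lie in {0, 1, 2, 3}")
    rng = substream(seed, "heights")
    h_p = float(rng.uniform(26.0, 34.0))
    rows = []
    for label, grade in zip(morphometry.VERTEBRAE, g):
        lo, hi = _BANDS[int(grade)]
        c = float(rng.uniform(lo, hi))
        h_a = h_p * (1.0 - c)
        # middle height between anterior and posterior: anterior wedge shape,
        # so the worst compression is exactly c
        h_m = h_p * (1.0 - c * float(rng.uniform(0.2, 1.0)))
        rows.append({"vertebra": label, "h_a": h_a, "h_m": h_m, "h_p": h_p})
    return pd.DataFrame(rows)
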