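"""The 45-variable analysis matrix: encoding, unit conversions, filtering, scaling.

The analysis design holds 45 columns per patient: eight continuous clinical
measurements, seven derived age/BMI/years-since-menopause bins, a derived
low-calcium-intake dichotomy, and fourteen yes/no risk factors each coded as
a *complement pair* (two columns that always sum to one).  Complement coding
lets a wrapper selector pick either polarity of a binary factor; either
member alone carries the full information.

Utilities cover the study's unit conventions (one alcohol unit = 8 g pure
alcohol; one standardised dietary serving ~ 300 mg calcium), complete-case
filtering (records with any missing field are dropped, never imputed), and
min-max scaling of continuous inputs to [0, 1] fitted on the training half
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class SchemaError(KeyError):
    """A required raw variable is absent or unknown."""


@dataclass(frozen=True)
class VariableSpec:
    name: str
    kind: str  # 'continuous' | 'binary'
    complement_of: str | None = None
    description: str = ""


#: Raw yes/no risk factors; each expands to a (yes, no) complement pair.
BINARY_FACTORS: tuple[tuple[str, str], ...] = (
    ("current_smoking", "current smoker"),
    ("previous_smoking", "ex-smoker"),
    ("alcohol_ge_3_units", "alcohol intake >= 3 units/day"),
    ("low_bmd", "bone mineral density T-score <= -2.5"),
    ("previous_fracture", "previous clinical fragility fracture"),
    ("family_hip_fracture", "family history of hip fracture"),
    ("hypertension", "arterial hypertension"),
    ("dyslipidemia", "dyslipidemia"),
    ("gastric_disease", "gastric/oesophagus disease"),
    ("anxiety_depression", "anxiety or depression"),
    ("copd", "chronic obstructive pulmonary disease"),
    ("osteoarthritis", "osteoarthritis"),
    ("kidney_stones", "history of kidney stones"),
    ("t2d", "type 2 diabetes mellitus"),
)

CONTINUOUS_VARS: tuple[tuple[str, str], ...] = (
    ("age", "age (years)"),
    ("age_at_menopause", "age at menopause (years)"),
    ("ysm", "years since menopause"),
    ("bmi", "body mass index (kg/m^2)"),
    ("calcium_mg_day", "daily dietary calcium intake (mg/day)"),
    ("pregnancies", "number of pregnancies"),
    ("breastfeeding_months", "months of breast feeding"),
    ("alcohol_units_per_day", "alcohol intake (units/day, 1 unit = 8 g)"),
)


def _build_dictionary() -> tuple[VariableSpec, ...]:
    specs: list[VariableSpec] = [
        VariableSpec(n, "continuous", description=d) for n, d in CONTINUOUS_VARS
    ]
    specs += [
        VariableSpec("age_lt_68", "binary", description="age < 68 years"),
        VariableSpec("age_ge_68", "binary", "age_lt_68", "age >= 68 years"),
        VariableSpec("bmi_le_21", "binary", description="BMI <= 21"),
        VariableSpec("bmi_21_30", "binary", description="21 < BMI < 30"),
        VariableSpec("bmi_ge_30", "binary", description="BMI >= 30"),
        VariableSpec("ysm_lt_18", "binary", description="years since menopause < 18"),
        VariableSpec("ysm_ge_18", "binary", "ysm_lt_18", "years since menopause >= 18"),
        VariableSpec("calcium_le_300_yes", "binary", description="calcium intake <= 300 mg/day"),
        VariableSpec("calcium_le_300_no", "binary", "calcium_le_300_yes",
                     "calcium intake > 300 mg/day"),
    ]
    for name, desc in BINARY_FACTORS:
        specs.append(VariableSpec(f"{name}_yes", "binary", description=desc))
        specs.append(VariableSpec(f"{name}_no", "binary", f"{name}_yes", f"no {desc}"))
    return tuple(specs)


#: The full 45-column analysis design, in canonical order.
DATA_DICTIONARY: tuple[VariableSpec, ...] = _build_dictionary()
FEATURE_NAMES: tuple[str, ...] = tuple(s.name for s in DATA_DICTIONARY)
CONTINUOUS_NAMES: tuple[str, ...] = tuple(
    s.name for s in DATA_DICTIONARY if s.kind == "continuous"
)

assert len(FEATURE_NAMES) == 45

#: Raw columns the encoder consumes.
RAW_REQUIRED: tuple[str, ...] = tuple(n for n, _ in CONTINUOUS_VARS[:2] + CONTINUOUS_VARS[3:]) + tuple(
    n for n, _ in BINARY_FACTORS if n != "alcohol_ge_3_units"
)


def alcohol_units(grams_per_day: float) -> tuple[float, bool, bool]:
    """Convert g/day pure alcohol to study units (8 g each).

    Returns (units/day, heavy-intake flag at >= 3 units/day, exclusion flag
    for intake above 100 g/day, treated as suspected secondary osteoporosis).
    """
    if grams_per_day < 0:
        raise ValueError("alcohol intake cannot be negative")
    units = grams_per_day / 8.0
    return units, units >= 3.0, grams_per_day > 100.0


def calcium_intake(weekly_servings: float) -> float:
    """mg/day of calcium from weekly standardised servings (~300 mg each)."""
    if weekly_servings < 0:
        raise ValueError("servings cannot be negative")
    return weekly_servings * 300.0 / 7.0


def encode_features(raw: pd.DataFrame) -> pd.DataFrame:
    """Expand raw clinical records into the 45-column analysis matrix.

    Derived bins use the design's boundary convention: the upper bin is
    closed at its printed cutpoint (age 68 -> 'age >= 68', YSM 18 ->
    'YSM >= 18', BMI 21 -> '<= 21', BMI 30 -> '>= 30').  Missing raw values
    propagate to every column derived from them.
    """
    missing = [c for c in RAW_REQUIRED if c not in raw.columns]
    if missing:
        raise SchemaError(f"raw records are missing required variables: {missing}")
    out = pd.DataFrame(index=raw.index)

    if "ysm" in raw.columns:
        ysm = raw["ysm"].astype(float)
    else:
        ysm = raw["age"].astype(float) - raw["age_at_menopause"].astype(float)
    age = raw["age"].astype(float)
    bmi = raw["bmi"].astype(float)
    calcium = raw["calcium_mg_day"].astype(float)
    units = raw["alcohol_units_per_day"].astype(float)

    out["age"] = age
    out["age_at_menopause"] = raw["age_at_menopause"].astype(float)
    out["ysm"] = ysm
    out["bmi"] = bmi
    out["calcium_mg_day"] = calcium
    out["pregnancies"] = raw["pregnancies"].astype(float)
    out["breastfeeding_months"] = raw["breastfeeding_months"].astype(float)
    out["alcohol_units_per_day"] = units

    def pair(yes: pd.Series, yes_col: str, no_col: str) -> None:
        out[yes_col] = yes.astype(float)
        out[no_col] = 1.0 - out[yes_col]

    def cut(cond: pd.Series, source: pd.Series) -> pd.Series:
        return cond.astype(float).mask(source.isna())

    out["age_lt_68"] = cut(age < 68, age)
    out["age_ge_68"] = cut(age >= 68, age)
    out["bmi_le_21"] = cut(bmi <= 21, bmi)
    out["bmi_21_30"] = cut((bmi > 21) & (bmi < 30), bmi)
    out["bmi_ge_30"] = cut(bmi >= 30, bmi)
    out["ysm_lt_18"] = cut(ysm < 18, ysm)
    out["ysm_ge_18"] = cut(ysm >= 18, ysm)
    pair(cut(calcium <= 300, calcium), "calcium_le_300_yes", "calcium_le_300_no")
    pair(cut(units >= 3, units), "alcohol_ge_3_units_yes", "alcohol_ge_3_units_no")
    for name, _ in BINARY_FACTORS:
        if name == "alcohol_ge_3_units":
            continue
        src = raw[name].astype(float)
        pair(src.mask(src.isna()), f"{name}_yes", f"{name}_no")

    return out[list(FEATURE_NAMES)]


def exclude_incomplete(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Complete-case filter: drop any record with one or more missing fields.

    Returns the kept records and an exclusion log (record index plus the
    names of its missing fields).  No imputation is attempted.
    """
    isna = records.isna()
    dropped = isna.any(axis=1)
    log = pd.DataFrame(
        {
            "record": records.index[dropped],
            "missing_fields": [
                ",".join(records.columns[row]) for row in isna.loc[dropped].to_numpy()
            ],
        }
    )
    kept = records.loc[~dropped].copy()
    if kept.empty and not records.empty:
        import warnings

        warnings.warn("complete-case filter removed every record", stacklevel=2)
    return kept, log


@dataclass
class MinMaxScaler:
    """Min-max scaler for continuous columns, fitted on the training half.

    Test-set values outside the training range clip to [0, 1]; binary
    columns pass through untouched so they stay exact complements.
    """

    columns: tuple[str, ...]
    mins: dict[str, float] = field(default_factory=dict)
    maxs: dict[str, float] = field(default_factory=dict)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for c in self.columns:
            lo, hi = self.mins[c], self.maxs[c]
            if hi > lo:
                out[c] = ((table[c] - lo) / (hi - lo)).clip(0.0, 1.0)
            else:
                out[c] = 0.0
        return out


def scale_inputs(
    table: pd.DataFrame, fit_on, continuous: tuple[str, ...] | None = None
) -> tuple[pd.DataFrame, MinMaxScaler]:
    """Scale continuous columns to [0, 1] using training-subset extremes only."""
    train = table.loc[fit_on] if not isinstance(fit_on, pd.DataFrame) else fit_on
    if train.empty:
        raise ValueError("training subset is empty")
    cols = tuple(c for c in (continuous or CONTINUOUS_NAMES) if c in table.columns)
    scaler = MinMaxScaler(columns=cols)
    for c in cols:
        lo, hi = float(train[c].min()), float(train[c].max())
        if hi <= lo:
            import warnings

            warnings.warn(f"constant column {c!r} scaled to 0", stacklevel=2)
        scaler.mins[c] = lo
        scaler.maxs[c] = hi
    return scaler.transform(table), scaler
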