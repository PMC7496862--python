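"""Synthetic post-transplant cohort generator.

No patient registry is distributed with this package, so every stage of
the pipeline is exercised on synthetic cohorts that reproduce the
published summary statistics of the four follow-up samples: sample
size, outcome mean/SD, age range 30-60, 2-6 years since transplant and
the diabetes-risk fraction.  Outcomes are drawn from a log-normal for
proteinuria (the printed SD exceeds the mean, implying strong right
skew) and a truncated normal on [0, 130] for GFR.  Glycaemia is a
two-component mixture: a normal-range component and an elevated
component whose weight equals the diabetes-risk fraction.  Drug levels
are uniform over their therapeutic ranges.  All randomness flows
through a single integer seed.

Measured outcomes are by default generated independently of the fuzzy
systems (the simulator does not assume the rule bases are true); an
optional FIS-consistent mode draws the outcome as multiplicative noise
around the FIS prediction, for positive-control testing.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clinical import mdrd_gfr
from .fuzzy_core import FISDefinition, NoRuleFired, infer

__all__ = [
    "PatientRecord",
    "CohortProfile",
    "PROFILES",
    "simulate_cohort",
    "apply_inclusion_criteria",
    "normalize_outcome",
    "cohort_to_frame",
    "frame_to_records",
]


@dataclass(frozen=True)
class PatientRecord:
    """Crisp clinical values for one patient at one follow-up visit."""

    id: str
    age: float
    years_since_transplant: float
    glycaemia: float
    sex: str = "M"
    sirolimus: float | None = None
    cyclosporine: float | None = None
    ace_dose_diff: float | None = None  # signed, dose-step units
    serum_creatinine: float | None = None
    measured_proteinuria: float | None = None
    measured_gfr: float | None = None
    diabetes_risk: bool = False

    def __post_init__(self) -> None:
        for name in ("age", "years_since_transplant", "glycaemia", "sirolimus",
                     "cyclosporine", "serum_creatinine", "measured_proteinuria",
                     "measured_gfr"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} cannot be negative: {v}")


@dataclass(frozen=True)
class CohortProfile:
    """Statistical description of one follow-up cohort to emulate."""

    name: str
    n: int
    outcome: str                 # "proteinuria" | "gfr"
    outcome_mean: float
    outcome_sd: float
    diabetes_fraction: float
    drug_field: str              # record field carrying the drug input
    drug_range: tuple[float, float]
    age_range: tuple[float, float] = (30.0, 60.0)
    years_range: tuple[float, float] = (2.0, 6.0)

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("cohort size must be positive")
        if self.outcome not in ("proteinuria", "gfr"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.outcome_mean <= 0 or self.outcome_sd < 0:
            raise ValueError("outcome mean must be positive, SD non-negative")
        if not 0.0 <= self.diabetes_fraction <= 1.0:
            raise ValueError("diabetes fraction must be in [0, 1]")


# Published summary statistics of the four follow-up samples.
PROFILES: dict[str, CohortProfile] = {
    "protfis": CohortProfile(
        name="protfis", n=63, outcome="proteinuria",
        outcome_mean=401.78, outcome_sd=424.19,
        diabetes_fraction=12 / 63, drug_field="sirolimus", drug_range=(1.0, 16.0),
    ),
    "gfrfis": CohortProfile(
        name="gfrfis", n=103, outcome="gfr",
        outcome_mean=65.98, outcome_sd=15.86,
        diabetes_fraction=38 / 103, drug_field="cyclosporine",
        drug_range=(0.5, 16.0),
    ),
    "protace": CohortProfile(
        name="protace", n=70, outcome="proteinuria",
        outcome_mean=532.00, outcome_sd=516.00,
        diabetes_fraction=13 / 70, drug_field="ace_dose_diff",
        drug_range=(-4.0, 0.0),
    ),
    "gfrace": CohortProfile(
        name="gfrace", n=107, outcome="gfr",
        outcome_mean=53.54, outcome_sd=16.22,
        diabetes_fraction=16 / 107, drug_field="ace_dose_diff",
        drug_range=(0.0, 4.0),
    ),
}

GFR_PHYSIOLOGICAL_RANGE = (0.0, 130.0)

# Glycaemia mixture components (mg/dL): normo-glycaemic follow-up patients
# cluster in the normal band; the diabetes-risk component sits above the
# impaired-fasting threshold with a heavier spread.
_GLYCAEMIA_NORMAL = (88.0, 10.0)
_GLYCAEMIA_ELEVATED = (150.0, 30.0)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Underlying (mu, sigma) of a log-normal with the given moments."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _draw_outcomes(profile: CohortProfile, rng: np.random.Generator) -> np.ndarray:
    if profile.outcome == "proteinuria":
        mu, sigma = _lognormal_params(profile.outcome_mean, profile.outcome_sd)
        return rng.lognormal(mu, sigma, size=profile.n)
    lo, hi = GFR_PHYSIOLOGICAL_RANGE
    if profile.outcome_sd == 0:
        return np.full(profile.n, profile.outcome_mean)
    a = (lo - profile.outcome_mean) / profile.outcome_sd
    b = (hi - profile.outcome_mean) / profile.outcome_sd
    dist = stats.truncnorm(a, b, loc=profile.outcome_mean, scale=profile.outcome_sd)
    return np.asarray(dist.rvs(size=profile.n, random_state=rng))


def _creatinine_for_gfr(gfr: float, age: float, sex: str) -> float:
    """Invert the MDRD equation for serum creatinine at a target eGFR."""
    base = mdrd_gfr(1.0, age, sex)
    return (gfr / base) ** (-1.0 / 1.154)


def simulate_cohort(
    profile: CohortProfile,
    seed: int,
    fis: FISDefinition | None = None,
    fis_noise_cv: float = 0.10,
) -> list[PatientRecord]:
    """Draw a reproducible synthetic cohort matching ``profile``.

    When ``fis`` is given, measured outcomes are re-drawn as
    log-normal multiplicative noise (coefficient of variation
    ``fis_noise_cv``) around the FIS prediction instead of being
    sampled independently (positive-control mode); records in rule-base
    gaps keep their independent draw.
    """
    rng = np.random.default_rng(seed)
    ages = rng.uniform(*profile.age_range, size=profile.n)
    years = rng.uniform(*profile.years_range, size=profile.n)
    sexes = rng.choice(["M", "F"], size=profile.n)
    diabetic = rng.random(profile.n) < profile.diabetes_fraction
    gly_normal = rng.normal(*_GLYCAEMIA_NORMAL, size=profile.n)
    gly_elev = rng.normal(*_GLYCAEMIA_ELEVATED, size=profile.n)
    glycaemia = np.clip(np.where(diabetic, gly_elev, gly_normal), 45.0, 295.0)
    drug = rng.uniform(*profile.drug_range, size=profile.n)
    outcomes = _draw_outcomes(profile, rng)
    noise = rng.lognormal(0.0, fis_noise_cv, size=profile.n)

    records = []
    for i in range(profile.n):
        fields: dict = {
            "id": f"{profile.name}-{i + 1:03d}",
            "age": float(ages[i]),
            "years_since_transplant": float(years[i]),
            "glycaemia": float(glycaemia[i]),
            "sex": str(sexes[i]),
            "diabetes_risk": bool(diabetic[i]),
            profile.drug_field: float(drug[i]),
        }
        outcome = float(outcomes[i])
        if fis is not None:
            inputs = {
                name: abs(fields[profile.drug_field]) if name == "diff_ace"
                else fields[name]
                for name in fis.input_names
            }
            try:
                outcome = float(infer(fis, inputs).crisp * noise[i])
            except NoRuleFired:
                pass
        if profile.outcome == "proteinuria":
            fields["measured_proteinuria"] = outcome
        else:
            outcome = float(np.clip(outcome, 1.0, GFR_PHYSIOLOGICAL_RANGE[1]))
            fields["measured_gfr"] = outcome
            fields["serum_creatinine"] = _creatinine_for_gfr(
                outcome, fields["age"], fields["sex"]
            )
        records.append(PatientRecord(**fields))
    return records


def apply_inclusion_criteria(
    records: Sequence[PatientRecord],
    required_fields: Sequence[str] = (),
    age_range: tuple[float, float] = (30.0, 60.0),
    years_range: tuple[float, float] = (2.0, 6.0),
) -> tuple[list[PatientRecord], list[tuple[PatientRecord, str]]]:
    """Partition records into (kept, excluded-with-reason).

    Inclusion requires age and time-since-transplant inside the study
    windows and presence of the system-relevant clinical fields.
    Idempotent and order-preserving.
    """
    kept: list[PatientRecord] = []
    excluded: list[tuple[PatientRecord, str]] = []
    for rec in records:
        if not age_range[0] <= rec.age <= age_range[1]:
            excluded.append((rec, "age"))
        elif not years_range[0] <= rec.years_since_transplant <= years_range[1]:
            excluded.append((rec, "time since transplant"))
        else:
            missing = [f for f in required_fields if getattr(rec, f, None) is None]
            if missing:
                excluded.append((rec, f"missing {', '.join(missing)}"))
            else:
                kept.append(rec)
    return kept, excluded


def normalize_outcome(value: float, divisor: float) -> float:
    """Unitless normalized outcome value/divisor (divisor must be positive).

    The normalization divisor is always an explicit argument: the
    published normalized means are not mutually consistent with any
    single divisor, so none is ever inferred.
    """
    if divisor <= 0:
        raise ValueError("normalization divisor must be positive")
    return value / divisor


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

COHORT_COLUMNS = [
    "id", "age", "years_since_transplant", "glycaemia", "sex",
    "sirolimus", "cyclosporine", "ace_dose_diff", "serum_creatinine",
    "measured_proteinuria", "measured_gfr", "diabetes_risk",
]


def cohort_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    frame = pd.DataFrame([asdict(r) for r in records])
    return frame.reindex(columns=COHORT_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[PatientRecord]:
    missing = [c for c in ("id", "age", "years_since_transplant", "glycaemia")
               if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort table lacks required column(s) {missing}")
    records = []
    for _, row in frame.iterrows():
        kwargs = {}
        for col in COHORT_COLUMNS:
            if col not in frame.columns:
                continue
            v = row[col]
            if pd.isna(v):
                continue
            if col == "diabetes_risk":
                v = bool(v) if not isinstance(v, str) else v.lower() in ("true", "1")
            elif col in ("id", "sex"):
                v = str(v)
            else:
                v = float(v)
            kwargs[col] = v
        records.append(PatientRecord(**kwargs))
    return records


def write_cohort_csv(records: Sequence[PatientRecord], path: str | Path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> list[PatientRecord]:
    return frame_to_records(pd.read_csv(path))
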