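"""Band-agreement scoring of FIS predictions against measured outcomes.

A prediction counts as correct when the crisp FIS output falls in the
same clinical risk band as the measured value (band agreement).  For
the binary sensitivity/specificity family the five-band task is
binarized as "any abnormality": a patient is positive when their band
ordinal is above the lowest-risk band.  A one-vs-rest macro-averaged
variant is exposed as an option.  Percentages are rounded half-up to
integers for report parity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .clinical import RiskBand
from .fuzzy_core import FISDefinition, NoRuleFired, infer

__all__ = [
    "ConfusionCounts",
    "EvaluationResult",
    "band_agreement",
    "evaluate_cohort",
    "metrics",
    "overestimation_gap",
    "round_half_up",
]

N_BANDS = 5


def round_half_up(x: float) -> int:
    """Round a non-negative percentage half-up (92.5 -> 93)."""
    return int(math.floor(x + 0.5))


@dataclass
class ConfusionCounts:
    """Binary confusion counts plus the full 5x5 band-agreement matrix."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    matrix: np.ndarray = field(
        default_factory=lambda: np.zeros((N_BANDS, N_BANDS), dtype=int)
    )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def add(self, predicted: RiskBand, measured: RiskBand) -> None:
        self.matrix[measured.ordinal, predicted.ordinal] += 1
        pred_pos = predicted.ordinal >= 1
        true_pos = measured.ordinal >= 1
        if true_pos and pred_pos:
            self.tp += 1
        elif true_pos and not pred_pos:
            self.fn += 1
        elif not true_pos and pred_pos:
            self.fp += 1
        else:
            self.tn += 1

    @property
    def band_correct(self) -> int:
        return int(np.trace(self.matrix))


def band_agreement(
    predicted: float, measured: float, band_fn: Callable[[float], RiskBand]
) -> bool:
    """True iff prediction and measurement fall in the same risk band."""
    return band_fn(predicted).ordinal == band_fn(measured).ordinal


def _record_inputs(fis: FISDefinition, record) -> dict[str, float]:
    """Map a patient record's fields onto the FIS input variables.

    The signed ACE dose difference is folded by absolute value onto the
    non-negative level scale.
    """
    values: dict[str, float] = {}
    for name in fis.input_names:
        attr = "ace_dose_diff" if name == "diff_ace" else name
        v = getattr(record, attr, None)
        if v is None:
            raise ValueError(
                f"record {getattr(record, 'id', '?')} lacks field {attr!r} "
                f"required by {fis.name}"
            )
        values[name] = abs(float(v)) if name == "diff_ace" else float(v)
    return values


def _measured_outcome(fis: FISDefinition, record) -> float:
    attr = f"measured_{fis.output.name}"
    v = getattr(record, attr, None)
    if v is None:
        raise ValueError(
            f"record {getattr(record, 'id', '?')} lacks measured outcome {attr!r}"
        )
    return float(v)


@dataclass
class EvaluationResult:
    """Cohort-level evaluation: per-record table, tallies and accuracy."""

    counts: ConfusionCounts
    records: pd.DataFrame
    no_fire: int

    @property
    def n_evaluated(self) -> int:
        return self.counts.total + self.no_fire

    @property
    def accuracy_percent(self) -> int:
        """Band-agreement accuracy, rounded half-up; no-fire counts as error."""
        if self.n_evaluated == 0:
            raise ValueError("no records evaluated")
        return round_half_up(100.0 * self.counts.band_correct / self.n_evaluated)

    @property
    def no_fire_frequency(self) -> float:
        return self.no_fire / self.n_evaluated if self.n_evaluated else 0.0


def evaluate_cohort(
    fis: FISDefinition,
    records: Sequence,
    band_fn: Callable[[float], RiskBand],
) -> EvaluationResult:
    """Run the FIS over a cohort and tally band agreement.

    Records where no rule fires are counted separately and treated as
    errors in the accuracy denominator (default policy).
    """
    counts = ConfusionCounts()
    rows = []
    no_fire = 0
    for rec in records:
        inputs = _record_inputs(fis, rec)
        measured = _measured_outcome(fis, rec)
        row = {"id": getattr(rec, "id", None), **inputs, "measured": measured}
        try:
            result = infer(fis, inputs)
        except NoRuleFired:
            no_fire += 1
            row.update(predicted=np.nan, predicted_band="no_rule_fired",
                       measured_band=band_fn(measured).label, agreement=False)
            rows.append(row)
            continue
        pred_band = band_fn(result.crisp)
        meas_band = band_fn(measured)
        counts.add(pred_band, meas_band)
        row.update(
            predicted=result.crisp,
            predicted_band=pred_band.label,
            measured_band=meas_band.label,
            agreement=pred_band.ordinal == meas_band.ordinal,
        )
        rows.append(row)
    return EvaluationResult(
        counts=counts, records=pd.DataFrame(rows), no_fire=no_fire
    )


def _pct(num: float, den: float) -> int | None:
    """Rounded percentage, or None when the ratio is undefined."""
    if den == 0:
        return None
    return round_half_up(100.0 * num / den)


def metrics(counts: ConfusionCounts) -> dict[str, int | None]:
    """Accuracy/sensitivity/specificity/precision/recall/F/G from counts.

    Undefined ratios (zero denominators) are reported as ``None``,
    never as a silent zero.
    """
    if counts.total == 0:
        raise ValueError("metrics require at least one evaluated record")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    sens = tp / (tp + fn) if tp + fn else None
    spec = tn / (tn + fp) if tn + fp else None
    prec = tp / (tp + fp) if tp + fp else None
    f = (
        2 * prec * sens / (prec + sens)
        if prec is not None and sens is not None and prec + sens > 0
        else None
    )
    g = math.sqrt(sens * spec) if sens is not None and spec is not None else None
    as_pct = lambda v: None if v is None else round_half_up(100.0 * v)
    return {
        "accuracy": _pct(tp + tn, counts.total),
        "sensitivity": as_pct(sens),
        "specificity": as_pct(spec),
        "precision": as_pct(prec),
        "recall": as_pct(sens),
        "f_measure": as_pct(f),
        "g_mean": as_pct(g),
    }


def overestimation_gap(predicted: float, measured: float) -> float:
    """Relative prediction gap, percent: 100 * |pred - meas| / meas."""
    if measured <= 0:
        raise ValueError("measured value must be positive")
    return 100.0 * abs(predicted - measured) / measured
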