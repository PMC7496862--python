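"""The four renal-transplant knowledge bases and their declarative I/O.

Encodes the fuzzy systems used for post-kidney-transplant follow-up:

* ``ProtFIS`` — glycaemia + sirolimus blood level -> predicted proteinuria
* ``GfrFIS`` — glycaemia + cyclosporine dose -> predicted GFR
* ``ProtACE`` — glycaemia + ACE-inhibitor dose-step decrease -> proteinuria
* ``GfrACE`` — glycaemia + ACE-inhibitor dose-step increase -> GFR

The published clinical thresholds fix the *bands* (glycaemia normal
70-99 / impaired 100-125 / diabetic >=126 mg/dL; proteinuria
150/500/1000/3000 mg/24 h; CKD stages at GFR 90/60/30/15 mL/min; the
EMA therapeutic windows for sirolimus and cyclosporine) but not the
membership-function vertices.  Vertices are reconstructed so adjacent
sets cross at degree 0.5 on each clinical boundary, with transition
half-widths of 10 mg/dL for glycaemia and 20% of the narrower adjacent
band for proteinuria; where printed drug ranges overlap, the plateau
is the non-overlapped core and the linear transition spans the printed
overlap.  A small set of vertices was calibrated once against the
published worked examples and frozen in the shipped configs (see
``docs/methods.md``): the sirolimus sufficient->good crossover sits at
8.5 ng/mL, the ACE dose-difference levels are asymmetric triangles
(k-0.5, k, k+1) so a fractional dose step counts toward the level
already completed, and the GFR transition half-widths are per-boundary
(3/12/4/6 mL/min at the 15/30/60/90 cutoffs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from itertools import product
from pathlib import Path
from typing import Iterable

import numpy as np

from .fuzzy_core import (
    ConfigurationError,
    FISDefinition,
    FuzzyRule,
    LinguisticVariable,
    MembershipFunction,
)

__all__ = [
    "SYSTEM_NAMES",
    "BandThresholds",
    "build_protfis",
    "build_gfrfis",
    "build_protace",
    "build_gfrace",
    "build_system",
    "load_fis_config",
    "save_fis_config",
    "shipped_config_path",
    "coverage_report",
]

SYSTEM_NAMES = ("protfis", "gfrfis", "protace", "gfrace")


@dataclass(frozen=True)
class BandThresholds:
    """Ordered clinical bands of one variable, lowest risk first."""

    variable: str
    bands: tuple[tuple[str, tuple[float, float]], ...]  # (label, (lo, hi))
    colors: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.colors) != len(self.bands):
            raise ConfigurationError("one colour per band required")


# ---------------------------------------------------------------------------
# Linguistic variables
# ---------------------------------------------------------------------------

def _tri(a, b, c, **kw):
    return MembershipFunction("triangular", (a, b, c), **kw)


def _trap(a, b, c, d, **kw):
    return MembershipFunction("trapezoidal", (a, b, c, d), **kw)


def glycaemia_variable() -> LinguisticVariable:
    """Blood glucose, mg/dL: normal / impaired-fasting / diabetic range."""
    return LinguisticVariable(
        name="glycaemia",
        universe=(40.0, 300.0),
        units="mg/dL",
        terms={
            "good": _trap(40, 40, 90, 110, left_shoulder=True),
            "alarm": _trap(90, 110, 116, 136),
            "danger": _trap(116, 136, 300, 300, right_shoulder=True),
        },
    )


def sirolimus_variable() -> LinguisticVariable:
    """Sirolimus trough blood level, ng/mL (EMA window 4-12)."""
    return LinguisticVariable(
        name="sirolimus",
        universe=(0.0, 20.0),
        units="ng/mL",
        terms={
            "alarm_down": _trap(0, 0, 4, 5, left_shoulder=True),
            "sufficient": _trap(4, 5, 6, 11),
            "good": _tri(6, 11, 12),
            "alarm_up": _trap(11, 12, 13, 14),
            "danger": _trap(13, 14, 20, 20, right_shoulder=True),
        },
    )


def cyclosporine_variable() -> LinguisticVariable:
    """Cyclosporine dose, mg/kg; risk grows with dose above the window."""
    return LinguisticVariable(
        name="cyclosporine",
        universe=(0.0, 20.0),
        units="mg/kg",
        terms={
            "alarm_down": _trap(0, 0, 1.5, 2, left_shoulder=True),
            "good": _trap(1.5, 2, 4, 5),
            "sufficient": _trap(4, 5, 8, 11),
            "alarm_up": _trap(8, 11, 12, 15),
            "danger": _trap(12, 15, 20, 20, right_shoulder=True),
        },
    )


def diff_ace_variable() -> LinguisticVariable:
    """ACE-inhibitor dose difference in dose-step levels 0..4 (magnitude).

    Levels are asymmetric triangles (k-0.5, k, k+1): a recorded
    difference halfway between two levels is attributed to the level
    already completed, never to the larger one (protective reading of a
    partial dose step).
    """
    return LinguisticVariable(
        name="diff_ace",
        universe=(0.0, 4.0),
        units="dose steps",
        terms={
            "0": _tri(0, 0, 1),
            "1": _tri(0.5, 1, 2),
            "2": _tri(1.5, 2, 3),
            "3": _tri(2.5, 3, 4),
            "4": _tri(3.5, 4, 4),
        },
    )


def proteinuria_variable() -> LinguisticVariable:
    """24-hour urinary protein, mg/24 h, five clinical bands."""
    return LinguisticVariable(
        name="proteinuria",
        universe=(0.0, 4000.0),
        units="mg/24 h",
        terms={
            "good": _trap(0, 0, 120, 180, left_shoulder=True),
            "sufficient": _trap(120, 180, 430, 570),
            "alterate": _trap(430, 570, 900, 1100),
            "alarm": _trap(900, 1100, 2800, 3200),
            "danger": _trap(2800, 3200, 4000, 4000, right_shoulder=True),
        },
    )


def gfr_variable() -> LinguisticVariable:
    """Glomerular filtration rate, mL/min, CKD stages 5..1 (risk order)."""
    return LinguisticVariable(
        name="gfr",
        universe=(0.0, 130.0),
        units="mL/min",
        terms={
            "danger": _trap(0, 0, 12, 18, left_shoulder=True),
            "alarm4": _tri(12, 18, 42),
            "alarm3": _trap(18, 42, 56, 64),
            "alarm2": _trap(56, 64, 84, 96),
            "good": _trap(84, 96, 130, 130, right_shoulder=True),
        },
    )


PROTEINURIA_BANDS = BandThresholds(
    variable="proteinuria",
    bands=(
        ("good", (0.0, 150.0)),
        ("sufficient", (150.0, 500.0)),
        ("alterate", (500.0, 1000.0)),
        ("alarm", (1000.0, 3000.0)),
        ("danger", (3000.0, 4000.0)),
    ),
    colors=("green", "yellow-green", "yellow", "orange", "red"),
)

GFR_BANDS = BandThresholds(
    variable="gfr",
    bands=(
        ("good", (90.0, 130.0)),
        ("alarm2", (60.0, 90.0)),
        ("alarm3", (30.0, 60.0)),
        ("alarm4", (15.0, 30.0)),
        ("danger", (0.0, 15.0)),
    ),
    colors=("green", "yellow-green", "yellow", "orange", "red"),
)

GLYCAEMIA_BANDS = BandThresholds(
    variable="glycaemia",
    bands=(
        ("good", (70.0, 99.0)),
        ("alarm", (100.0, 125.0)),
        ("danger", (126.0, 300.0)),
    ),
    colors=("green", "orange", "red"),
)


# ---------------------------------------------------------------------------
# Rule tables
# ---------------------------------------------------------------------------

def _rules(var_a: str, var_b: str, table: Iterable[tuple[str | None, str, str]]):
    out = []
    for a, b, cons in table:
        clauses = [] if a is None else [(var_a, a)]
        clauses.append((var_b, b))
        out.append(FuzzyRule(antecedent=tuple(clauses), consequent=cons))
    return tuple(out)


def build_protfis() -> FISDefinition:
    """Proteinuria predictor from glycaemia and sirolimus blood level."""
    rules = _rules("glycaemia", "sirolimus", [
        ("good", "good", "good"),
        ("danger", "danger", "danger"),
        ("good", "sufficient", "sufficient"),
        ("alarm", "alarm_up", "alarm"),
        ("alarm", "sufficient", "alterate"),
        ("good", "alarm_up", "alterate"),
        ("alarm", "good", "sufficient"),
        ("good", "alarm_down", "sufficient"),
    ])
    return FISDefinition(
        name="ProtFIS",
        inputs=(glycaemia_variable(), sirolimus_variable()),
        output=proteinuria_variable(),
        rules=rules,
    )


def build_gfrfis() -> FISDefinition:
    """GFR predictor from glycaemia and cyclosporine dose."""
    rules = _rules("glycaemia", "cyclosporine", [
        ("danger", "danger", "danger"),
        ("good", "danger", "alarm3"),
        ("alarm", "alarm_up", "alarm4"),
        ("good", "sufficient", "alarm2"),
        ("good", "good", "good"),
        ("alarm", "good", "alarm2"),
        ("danger", "good", "alarm3"),
    ])
    return FISDefinition(
        name="GfrFIS",
        inputs=(glycaemia_variable(), cyclosporine_variable()),
        output=gfr_variable(),
        rules=rules,
    )


def build_protace() -> FISDefinition:
    """Proteinuria predictor from glycaemia and ACE-inhibitor dose decrease.

    Rule 1 constrains only the dose difference (wildcard glycaemia).
    """
    rules = _rules("glycaemia", "diff_ace", [
        (None, "2", "sufficient"),
        ("good", "1", "sufficient"),
        ("alarm", "1", "alterate"),
        ("danger", "1", "alarm"),
        ("alarm", "3", "alarm"),
        ("good", "3", "alterate"),
        ("danger", "4", "danger"),
        ("good", "0", "good"),
    ])
    return FISDefinition(
        name="ProtACE",
        inputs=(glycaemia_variable(), diff_ace_variable()),
        output=proteinuria_variable(),
        rules=rules,
    )


def build_gfrace() -> FISDefinition:
    """GFR predictor from glycaemia and ACE-inhibitor dose increase."""
    rules = _rules("glycaemia", "diff_ace", [
        ("good", "2", "alarm3"),
        ("alarm", "2", "alarm3"),
        ("good", "1", "alarm2"),
        ("alarm", "1", "alarm2"),
        ("good", "3", "alarm3"),
        ("danger", "3", "alarm4"),
        ("good", "4", "alarm2"),
        ("good", "0", "good"),
        ("danger", "4", "danger"),
    ])
    return FISDefinition(
        name="GfrACE",
        inputs=(glycaemia_variable(), diff_ace_variable()),
        output=gfr_variable(),
        rules=rules,
    )


_BUILDERS = {
    "protfis": build_protfis,
    "gfrfis": build_gfrfis,
    "protace": build_protace,
    "gfrace": build_gfrace,
}


def build_system(name: str) -> FISDefinition:
    """Build one of the four shipped systems by (case-insensitive) name."""
    key = name.lower()
    if key not in _BUILDERS:
        raise ConfigurationError(
            f"unknown system {name!r}; expected one of {SYSTEM_NAMES}"
        )
    return _BUILDERS[key]()


# ---------------------------------------------------------------------------
# Declarative JSON configuration
# ---------------------------------------------------------------------------

def _mf_to_dict(mf: MembershipFunction) -> dict:
    d = {"shape": mf.shape, "points": list(mf.points)}
    if mf.left_shoulder:
        d["left_shoulder"] = True
    if mf.right_shoulder:
        d["right_shoulder"] = True
    return d


def _var_to_dict(var: LinguisticVariable) -> dict:
    return {
        "name": var.name,
        "units": var.units,
        "universe": list(var.universe),
        "terms": [
            {"label": label, **_mf_to_dict(mf)} for label, mf in var.terms.items()
        ],
    }


def fis_to_dict(fis: FISDefinition) -> dict:
    return {
        "name": fis.name,
        "resolution": fis.resolution,
        "no_fire_policy": fis.no_fire_policy,
        "inputs": [_var_to_dict(v) for v in fis.inputs],
        "output": _var_to_dict(fis.output),
        "rules": [
            {
                "if": [[v, t] for v, t in r.antecedent],
                "connective": r.connective,
                "then": r.consequent,
                "weight": r.weight,
            }
            for r in fis.rules
        ],
    }


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(f"invalid FIS config: {msg}")


def _var_from_dict(d: dict, where: str) -> LinguisticVariable:
    _require(isinstance(d, dict), f"{where} must be an object")
    for key in ("name", "universe", "terms"):
        _require(key in d, f"{where} missing field {key!r}")
    _require(
        isinstance(d["universe"], (list, tuple)) and len(d["universe"]) == 2,
        f"{where}.universe must be [lo, hi]",
    )
    terms: dict[str, MembershipFunction] = {}
    _require(isinstance(d["terms"], list) and d["terms"],
             f"{where}.terms must be a non-empty list")
    for i, t in enumerate(d["terms"]):
        tw = f"{where}.terms[{i}]"
        for key in ("label", "shape", "points"):
            _require(key in t, f"{tw} missing field {key!r}")
        _require(t["label"] not in terms, f"{tw}: duplicate term label {t['label']!r}")
        terms[str(t["label"])] = MembershipFunction(
            shape=t["shape"],
            points=tuple(t["points"]),
            left_shoulder=bool(t.get("left_shoulder", False)),
            right_shoulder=bool(t.get("right_shoulder", False)),
        )
    return LinguisticVariable(
        name=str(d["name"]),
        universe=(float(d["universe"][0]), float(d["universe"][1])),
        terms=terms,
        units=str(d.get("units", "")),
    )


def fis_from_dict(doc: dict) -> FISDefinition:
    _require(isinstance(doc, dict), "document must be a JSON object")
    for key in ("name", "inputs", "output", "rules"):
        _require(key in doc, f"missing top-level field {key!r}")
    _require(isinstance(doc["inputs"], list) and doc["inputs"],
             "'inputs' must be a non-empty list")
    inputs = tuple(
        _var_from_dict(v, f"inputs[{i}]") for i, v in enumerate(doc["inputs"])
    )
    output = _var_from_dict(doc["output"], "output")
    rules = []
    _require(isinstance(doc["rules"], list) and doc["rules"],
             "'rules' must be a non-empty list")
    for i, r in enumerate(doc["rules"]):
        rw = f"rules[{i}]"
        for key in ("if", "then"):
            _require(key in r, f"{rw} missing field {key!r}")
        _require(isinstance(r["if"], list) and r["if"],
                 f"{rw}.if must be a non-empty list of [variable, term] pairs")
        rules.append(
            FuzzyRule(
                antecedent=tuple((str(v), str(t)) for v, t in r["if"]),
                consequent=str(r["then"]),
                connective=str(r.get("connective", "AND")),
                weight=float(r.get("weight", 1.0)),
            )
        )
    return FISDefinition(
        name=str(doc["name"]),
        inputs=inputs,
        output=output,
        rules=tuple(rules),
        resolution=int(doc.get("resolution", 2001)),
        no_fire_policy=str(doc.get("no_fire_policy", "error")),
    )


def save_fis_config(fis: FISDefinition, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fis_to_dict(fis), indent=1) + "\n")


def load_fis_config(path: str | Path) -> FISDefinition:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ConfigurationError(f"invalid FIS config: not valid JSON ({exc})")
    return fis_from_dict(doc)


def shipped_config_path(system: str) -> Path:
    """Filesystem path of the versioned config shipped with the package."""
    key = system.lower()
    if key not in SYSTEM_NAMES:
        raise ConfigurationError(
            f"unknown system {system!r}; expected one of {SYSTEM_NAMES}"
        )
    return Path(str(resources.files("renalfis") / "configs" / f"{key}.json"))


# ---------------------------------------------------------------------------
# Rule-base coverage
# ---------------------------------------------------------------------------

def coverage_report(
    fis: FISDefinition, grid_density: int = 41, threshold: float = 0.0
) -> list[dict]:
    """Input-space grid cells where no rule fires above ``threshold``.

    The shipped rule tables are partial (some term combinations have no
    rule), so silent gaps are a real safety concern; this scan makes
    them visible.  Deterministic and independent of rule order.
    """
    axes = [np.linspace(v.universe[0], v.universe[1], grid_density) for v in fis.inputs]
    gaps = []
    for point in product(*axes):
        fuzzified = {
            v.name: v.fuzzify(x) for v, x in zip(fis.inputs, point)
        }
        best = max(rule.strength(fuzzified) for rule in fis.rules)
        if best <= threshold:
            gaps.append({
                "inputs": {v.name: float(x) for v, x in zip(fis.inputs, point)},
                "max_strength": float(best),
            })
    return gaps
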