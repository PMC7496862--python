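"""Generic Mamdani-type fuzzy inference engine.

Implements the classical multi-input single-output Mamdani scheme:
crisp inputs are fuzzified through piecewise-linear (triangular or
trapezoidal) membership functions, rule firing strengths are computed
with min (AND) / max (OR), consequents are clipped by min-implication,
clipped sets are aggregated pointwise with max, and the aggregate is
defuzzified by its discrete centre of gravity (COG) over a sampled
output universe.

All operations are deterministic pure functions of their arguments; no
randomness is involved anywhere in the engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigurationError",
    "NoRuleFired",
    "MembershipFunction",
    "LinguisticVariable",
    "FuzzyRule",
    "FISDefinition",
    "InferenceResult",
    "implicate",
    "aggregate",
    "defuzzify_cog",
    "infer",
    "trace_report",
]


class ConfigurationError(ValueError):
    """A fuzzy-system definition is structurally invalid."""


class NoRuleFired(RuntimeError):
    """No rule attained a positive firing strength for the given inputs.

    Carries the per-variable fuzzified degrees so the caller can see
    which term combination fell into a gap of the rule base.
    """

    def __init__(self, fis_name: str, fuzzified: Mapping[str, Mapping[str, float]]):
        self.fis_name = fis_name
        self.fuzzified = {v: dict(t) for v, t in fuzzified.items()}
        detail = "; ".join(
            f"{var}: " + ", ".join(f"{term}={deg:.3f}" for term, deg in terms.items())
            for var, terms in self.fuzzified.items()
        )
        super().__init__(
            f"no rule of {fis_name!r} fired for the given inputs ({detail})"
        )


@dataclass(frozen=True)
class MembershipFunction:
    """One triangular or trapezoidal fuzzy set over a variable's universe.

    ``points`` are the breakpoints in universe units: ``(a, b, c)`` for a
    triangle with peak ``b``, ``(a, b, c, d)`` for a trapezoid with
    plateau ``[b, c]``.  A shoulder flag extends the plateau to the
    corresponding universe edge (degree 1 beyond the plateau instead of
    falling back to 0).  Degenerate equal breakpoints (``a == b`` or
    ``c == d``) denote a vertical edge.
    """

    shape: str  # "triangular" | "trapezoidal"
    points: tuple[float, ...]
    left_shoulder: bool = False
    right_shoulder: bool = False

    def __post_init__(self) -> None:
        if self.shape not in ("triangular", "trapezoidal"):
            raise ConfigurationError(f"unknown MF shape {self.shape!r}")
        n = {"triangular": 3, "trapezoidal": 4}[self.shape]
        if len(self.points) != n:
            raise ConfigurationError(
                f"{self.shape} MF needs {n} breakpoints, got {len(self.points)}"
            )
        pts = tuple(float(p) for p in self.points)
        if any(not np.isfinite(p) for p in pts):
            raise ConfigurationError("MF breakpoints must be finite")
        if any(q < p for p, q in zip(pts, pts[1:])):
            raise ConfigurationError(f"MF breakpoints must be non-decreasing: {pts}")
        object.__setattr__(self, "points", pts)

    @property
    def _abcd(self) -> tuple[float, float, float, float]:
        if self.shape == "triangular":
            a, b, c = self.points
            return a, b, b, c
        return self.points  # type: ignore[return-value]

    def degree(self, x) -> np.ndarray | float:
        """Piecewise-linear membership degree of ``x``; exact at breakpoints."""
        a, b, c, d = self._abcd
        xv = np.asarray(x, dtype=float)
        if self.left_shoulder or a == b:
            up = np.where(xv >= b, 1.0, 1.0 if self.left_shoulder else 0.0)
        else:
            up = np.clip((xv - a) / (b - a), 0.0, 1.0)
        if self.right_shoulder or c == d:
            down = np.where(xv <= c, 1.0, 1.0 if self.right_shoulder else 0.0)
        else:
            down = np.clip((d - xv) / (d - c), 0.0, 1.0)
        deg = np.minimum(up, down)
        return float(deg) if np.isscalar(x) or deg.ndim == 0 else deg

    @property
    def support(self) -> tuple[float, float]:
        a, _, _, d = self._abcd
        return (-np.inf if self.left_shoulder else a,
                np.inf if self.right_shoulder else d)


def mf_degree(mf: MembershipFunction, x: float) -> float:
    """Membership degree of crisp ``x`` in ``mf`` (functional alias)."""
    if not np.isfinite(x):
        raise ValueError(f"input value must be finite, got {x}")
    return float(mf.degree(float(x)))


@dataclass(frozen=True)
class LinguisticVariable:
    """A named variable whose values are labelled fuzzy sets.

    ``terms`` is an *ordered* mapping term label -> membership function;
    the order is the clinical risk/position order and is preserved in
    reports and serialization.
    """

    name: str
    universe: tuple[float, float]
    terms: dict[str, MembershipFunction]
    units: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.universe
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ConfigurationError(
                f"variable {self.name!r}: universe must be a non-empty interval"
            )
        if not self.terms:
            raise ConfigurationError(f"variable {self.name!r} has no terms")
        object.__setattr__(self, "universe", (float(lo), float(hi)))

    def clamp(self, x: float) -> float:
        lo, hi = self.universe
        if x < lo or x > hi:
            logger.warning(
                "%s=%g outside universe [%g, %g]; clamped", self.name, x, lo, hi
            )
            return min(max(x, lo), hi)
        return x

    def fuzzify(self, x: float) -> dict[str, float]:
        """Map a crisp value to a degree per term (out-of-range values clamped)."""
        if not np.isfinite(x):
            raise ValueError(f"{self.name}: input must be finite, got {x}")
        xc = self.clamp(float(x))
        return {label: float(mf.degree(xc)) for label, mf in self.terms.items()}

    def grid(self, resolution: int) -> np.ndarray:
        return np.linspace(self.universe[0], self.universe[1], resolution)

    def coverage_gaps(self, resolution: int = 1001) -> np.ndarray:
        """Universe points where no term has positive degree (should be empty)."""
        g = self.grid(resolution)
        total = np.zeros_like(g)
        for mf in self.terms.values():
            total = np.maximum(total, np.asarray(mf.degree(g)))
        return g[total <= 0.0]


def fuzzify(var: LinguisticVariable, x: float) -> dict[str, float]:
    return var.fuzzify(x)


@dataclass(frozen=True)
class FuzzyRule:
    """One "if antecedent then consequent" rule.

    The antecedent is a list of (variable, term) clauses joined by one
    connective; a variable absent from the antecedent is unconstrained
    (wildcard).  The consequent names a term of the single output
    variable.  Weight scales the firing strength (all shipped rules use
    weight 1).
    """

    antecedent: tuple[tuple[str, str], ...]
    consequent: str
    connective: str = "AND"
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.antecedent:
            raise ConfigurationError("rule needs at least one antecedent clause")
        if self.connective not in ("AND", "OR"):
            raise ConfigurationError(f"unknown connective {self.connective!r}")
        if not (0.0 < self.weight <= 1.0):
            raise ConfigurationError(f"rule weight must be in (0, 1]: {self.weight}")
        object.__setattr__(
            self, "antecedent", tuple((str(v), str(t)) for v, t in self.antecedent)
        )

    def strength(self, fuzzified: Mapping[str, Mapping[str, float]]) -> float:
        """Firing strength: min over clauses for AND, max for OR, times weight."""
        degs = []
        for var, term in self.antecedent:
            if var not in fuzzified:
                raise ConfigurationError(f"rule references unknown variable {var!r}")
            if term not in fuzzified[var]:
                raise ConfigurationError(
                    f"rule references unknown term {term!r} of variable {var!r}"
                )
            degs.append(fuzzified[var][term])
        alpha = min(degs) if self.connective == "AND" else max(degs)
        return alpha * self.weight


def rule_strength(
    rule: FuzzyRule, fuzzified: Mapping[str, Mapping[str, float]]
) -> float:
    return rule.strength(fuzzified)


@dataclass(frozen=True)
class FISDefinition:
    """A complete multi-input single-output Mamdani system definition."""

    name: str
    inputs: tuple[LinguisticVariable, ...]
    output: LinguisticVariable
    rules: tuple[FuzzyRule, ...]
    resolution: int = 2001
    no_fire_policy: str = "error"  # "error" | "nearest"

    def __post_init__(self) -> None:
        object.__setattr__(self, "inputs", tuple(self.inputs))
        object.__setattr__(self, "rules", tuple(self.rules))
        if self.resolution < 101:
            raise ConfigurationError("defuzzification resolution must be >= 101")
        if self.no_fire_policy not in ("error", "nearest"):
            raise ConfigurationError(
                f"unknown no-fire policy {self.no_fire_policy!r}"
            )
        names = [v.name for v in self.inputs]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate input variable names")
        for rule in self.rules:
            for var, term in rule.antecedent:
                iv = self.input_by_name(var)
                if iv is None:
                    raise ConfigurationError(
                        f"{self.name}: rule references unknown input {var!r}"
                    )
                if term not in iv.terms:
                    raise ConfigurationError(
                        f"{self.name}: input {var!r} has no term {term!r}"
                    )
            if rule.consequent not in self.output.terms:
                raise ConfigurationError(
                    f"{self.name}: output has no term {rule.consequent!r}"
                )

    def input_by_name(self, name: str) -> LinguisticVariable | None:
        for v in self.inputs:
            if v.name == name:
                return v
        return None

    @property
    def input_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.inputs)


@dataclass(frozen=True)
class InferenceResult:
    """Outcome of one Mamdani inference run."""

    crisp: float
    firing: tuple[float, ...]
    grid: np.ndarray = field(repr=False)
    curve: np.ndarray = field(repr=False)
    fuzzified: dict[str, dict[str, float]] = field(repr=False, default_factory=dict)
    output_term: str = ""

    @property
    def fired_count(self) -> int:
        return sum(1 for a in self.firing if a > 0.0)


def implicate(
    alpha: float, mf: MembershipFunction, grid: np.ndarray
) -> np.ndarray:
    """Min-implication: clip the consequent set at the firing strength."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"firing strength must be in [0, 1], got {alpha}")
    return np.minimum(alpha, np.asarray(mf.degree(grid), dtype=float))


def aggregate(curves: Iterable[np.ndarray], grid: np.ndarray) -> np.ndarray:
    """Pointwise-max aggregation of clipped consequent curves."""
    out = np.zeros_like(np.asarray(grid, dtype=float))
    for c in curves:
        c = np.asarray(c, dtype=float)
        if c.shape != out.shape:
            raise ConfigurationError("aggregate: curves sampled on different grids")
        out = np.maximum(out, c)
    return out


def defuzzify_cog(curve: np.ndarray, grid: np.ndarray) -> float:
    """Centre of gravity int(y*mu) / int(mu) of the sampled aggregate set.

    Integrals use trapezoidal quadrature on the sampled grid, which is
    exact for piecewise-linear curves whose breakpoints fall on grid
    nodes and avoids the half-sample edge bias of a plain sum when the
    aggregate set touches a universe boundary.
    """
    curve = np.asarray(curve, dtype=float)
    grid = np.asarray(grid, dtype=float)
    total = float(np.trapezoid(curve, grid))
    if total <= 0.0:
        raise ValueError("cannot defuzzify an identically-zero curve")
    return float(np.trapezoid(grid * curve, grid) / total)


def infer(fis: FISDefinition, inputs: Mapping[str, float]) -> InferenceResult:
    """Run fuzzify -> rule evaluation -> implication -> aggregation -> COG.

    ``inputs`` must provide one crisp value per input variable.  Raises
    :class:`NoRuleFired` (under the default policy) when the inputs fall
    into a gap of the rule base.
    """
    missing = [n for n in fis.input_names if n not in inputs]
    if missing:
        raise ValueError(f"{fis.name}: missing input(s) {missing}")
    fuzzified = {v.name: v.fuzzify(float(inputs[v.name])) for v in fis.inputs}

    firing = tuple(rule.strength(fuzzified) for rule in fis.rules)
    grid = fis.output.grid(fis.resolution)
    clipped = [
        implicate(alpha, fis.output.terms[rule.consequent], grid)
        for alpha, rule in zip(firing, fis.rules)
    ]
    curve = aggregate(clipped, grid)

    if not np.any(curve > 0.0):
        if fis.no_fire_policy == "error":
            raise NoRuleFired(fis.name, fuzzified)
        # nearest-band fallback: take the consequent of the rule whose
        # antecedent comes closest to firing and return its centroid.
        best = int(np.argmax([
            max((min(fuzzified[v][t] for v, t in r.antecedent), 0.0))
            if r.connective == "AND"
            else max(fuzzified[v][t] for v, t in r.antecedent)
            for r in fis.rules
        ]))
        mf = fis.output.terms[fis.rules[best].consequent]
        curve = np.asarray(mf.degree(grid), dtype=float)

    crisp = defuzzify_cog(curve, grid)
    out_term = max(fis.output.terms, key=lambda t: fis.output.terms[t].degree(crisp))
    return InferenceResult(
        crisp=crisp,
        firing=firing,
        grid=grid,
        curve=curve,
        fuzzified=fuzzified,
        output_term=out_term,
    )


def trace_report(result: InferenceResult, fis: FISDefinition) -> str:
    """Text surrogate of a graphical rule viewer: one row per rule."""
    lines = [f"{fis.name}: rule trace"]
    header = f"{'rule':>4}  {'antecedent':<52} {'alpha':>6}  consequent"
    lines.append(header)
    lines.append("-" * len(header))
    for i, (rule, alpha) in enumerate(zip(fis.rules, result.firing), start=1):
        clauses = f" {rule.connective} ".join(
            f"{var} is {term} ({result.fuzzified[var][term]:.3f})"
            for var, term in rule.antecedent
        )
        lines.append(
            f"{i:>4}  {clauses:<52} {alpha:6.3f}  {fis.output.name} is {rule.consequent}"
        )
    lines.append(
        f"crisp output: {result.crisp:.2f} {fis.output.units} "
        f"-> term {result.output_term!r} ({result.fired_count} rule(s) fired)"
    )
    return "\n".join(lines)
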