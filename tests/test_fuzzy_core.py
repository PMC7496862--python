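"""Unit and property tests for the Mamdani inference engine."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from renalfis.fuzzy_core import (
    ConfigurationError,
    FISDefinition,
    FuzzyRule,
    LinguisticVariable,
    MembershipFunction,
    NoRuleFired,
    aggregate,
    defuzzify_cog,
    implicate,
    infer,
    mf_degree,
    rule_strength,
    trace_report,
)

from conftest import clipped_trapezoid_nodes, piecewise_linear_centroid


def trap(a, b, c, d, **kw):
    return MembershipFunction("trapezoidal", (a, b, c, d), **kw)


def tri(a, b, c, **kw):
    return MembershipFunction("triangular", (a, b, c), **kw)


# --- membership degrees -----------------------------------------------------

@pytest.mark.parametrize(
    "x, expected",
    [(9.0, 1.0), (6.0, 0.0), (6.5, 0.5), (11.0, 1.0), (12.0, 0.0), (11.5, 0.5)],
)
def test_trapezoid_degree_piecewise_linear(x, expected):
    """Plateau is exactly 1, support edges exactly 0, linear in between."""
    assert mf_degree(trap(6, 7, 11, 12), x) == pytest.approx(expected)


def test_shoulder_extends_plateau_to_universe_edge():
    mf = trap(0, 0, 4, 5, left_shoulder=True)
    assert mf_degree(mf, -3.0) == 1.0
    assert mf_degree(mf, 4.0) == 1.0
    assert mf_degree(mf, 5.0) == 0.0
    right = trap(13, 14, 20, 20, right_shoulder=True)
    assert mf_degree(right, 25.0) == 1.0
    assert mf_degree(right, 13.0) == 0.0


def test_triangle_peak_and_edge_degrees():
    mf = tri(0, 0, 1)  # degenerate left edge
    assert mf_degree(mf, 0.0) == 1.0
    assert mf_degree(mf, 0.5) == 0.5
    assert mf_degree(mf, 1.0) == 0.0


def test_malformed_breakpoints_rejected():
    with pytest.raises(ConfigurationError):
        trap(5, 4, 3, 2)
    with pytest.raises(ConfigurationError):
        MembershipFunction("trapezoidal", (1, 2, 3))
    with pytest.raises(ConfigurationError):
        MembershipFunction("gaussian", (0, 1, 2))


@given(
    pts=st.lists(
        st.floats(min_value=-50, max_value=50, allow_nan=False), min_size=4, max_size=4
    ),
    x=st.floats(min_value=-100, max_value=100, allow_nan=False),
)
def test_degree_always_in_unit_interval(pts, x):
    """Any finite input maps to a degree in [0, 1] for any valid MF."""
    mf = trap(*sorted(pts))
    assert 0.0 <= mf_degree(mf, x) <= 1.0


# --- fuzzification ----------------------------------------------------------

def var_glycaemia():
    return LinguisticVariable(
        "glycaemia", (40, 300),
        {
            "good": trap(40, 40, 90, 110, left_shoulder=True),
            "alarm": trap(90, 110, 116, 136),
            "danger": trap(116, 136, 300, 300, right_shoulder=True),
        },
        units="mg/dL",
    )


def test_fuzzify_glycaemia_plateau_point():
    degrees = var_glycaemia().fuzzify(90.0)
    assert degrees == {"good": 1.0, "alarm": 0.0, "danger": 0.0}


def test_fuzzify_category_boundary_crosses_at_half():
    degrees = var_glycaemia().fuzzify(100.0)
    assert degrees["good"] == pytest.approx(0.5)
    assert degrees["alarm"] == pytest.approx(0.5)


def test_fuzzify_clamps_out_of_universe_values():
    inside = var_glycaemia().fuzzify(300.0)
    outside = var_glycaemia().fuzzify(350.0)
    assert outside == inside
    assert outside["danger"] == 1.0


def test_empty_term_set_is_configuration_error():
    with pytest.raises(ConfigurationError):
        LinguisticVariable("x", (0, 1), {})


# --- rule strength ----------------------------------------------------------

FUZZ = {"a": {"hi": 1.0, "lo": 0.6}, "b": {"hi": 0.2, "lo": 0.9}}


@pytest.mark.parametrize(
    "clauses, connective, weight, expected",
    [
        ((("a", "hi"), ("a", "lo")), "AND", 1.0, 0.6),
        ((("b", "hi"), ("b", "lo")), "OR", 1.0, 0.9),
        ((("a", "lo"), ("b", "lo")), "AND", 0.5, 0.3),
        ((("b", "hi"),), "AND", 1.0, 0.2),  # single clause = its own degree
    ],
)
def test_rule_strength_min_and_max_or(clauses, connective, weight, expected):
    rule = FuzzyRule(clauses, "out", connective=connective, weight=weight)
    assert rule_strength(rule, FUZZ) == pytest.approx(expected)


def test_rule_strength_unknown_reference_raises():
    rule = FuzzyRule((("a", "missing"),), "out")
    with pytest.raises(ConfigurationError):
        rule_strength(rule, FUZZ)
    rule = FuzzyRule((("nope", "hi"),), "out")
    with pytest.raises(ConfigurationError):
        rule_strength(rule, FUZZ)


@given(
    d1=st.floats(0, 1), d2=st.floats(0, 1), d3=st.floats(0, 1),
)
def test_and_strength_never_exceeds_any_clause_degree(d1, d2, d3):
    fuzz = {"v": {"t1": d1, "t2": d2, "t3": d3}}
    rule = FuzzyRule((("v", "t1"), ("v", "t2"), ("v", "t3")), "out")
    alpha = rule_strength(rule, fuzz)
    assert alpha <= min(d1, d2, d3) + 1e-12
    rule_or = FuzzyRule((("v", "t1"), ("v", "t2"), ("v", "t3")), "out",
                        connective="OR")
    assert rule_or.strength(fuzz) == pytest.approx(max(d1, d2, d3))


# --- implication and aggregation -------------------------------------------

def test_implicate_clips_consequent_at_strength():
    grid = np.linspace(0, 20, 401)
    mf = trap(6, 7, 11, 12)
    assert np.all(implicate(0.0, mf, grid) == 0.0)
    np.testing.assert_allclose(implicate(1.0, mf, grid), mf.degree(grid))
    clipped = implicate(0.6, mf, grid)
    assert clipped.max() == pytest.approx(0.6)
    np.testing.assert_allclose(clipped, np.minimum(0.6, mf.degree(grid)))


def test_aggregate_is_pointwise_max():
    grid = np.linspace(0, 10, 201)
    c1 = implicate(0.7, trap(0, 2, 4, 6), grid)
    c2 = implicate(0.4, trap(3, 5, 7, 9), grid)
    agg = aggregate([c1, c2], grid)
    np.testing.assert_allclose(agg, np.maximum(c1, c2))
    np.testing.assert_allclose(aggregate([c1], grid), c1)
    np.testing.assert_allclose(aggregate([c1, np.zeros_like(grid)], grid), c1)
    assert np.all(aggregate([], grid) == 0.0)


def test_aggregate_rejects_mismatched_grids():
    with pytest.raises(ConfigurationError):
        aggregate([np.zeros(5)], np.linspace(0, 1, 7))


# --- defuzzification --------------------------------------------------------

def test_cog_of_symmetric_clipped_triangle_is_its_centre():
    grid = np.linspace(0, 100, 2001)
    for alpha in (1.0, 0.5, 0.1):
        curve = implicate(alpha, tri(20, 50, 80), grid)
        assert defuzzify_cog(curve, grid) == pytest.approx(50.0, abs=1e-6)


def test_cog_matches_closed_form_centroid_of_printed_example():
    """Trapezoid (0,1)-(150,1)-(500,0) on [0, 4000] has centroid ~178.2."""
    oracle = piecewise_linear_centroid([(0, 1.0), (150, 1.0), (500, 0.0)])
    assert oracle == pytest.approx(178.2, abs=0.05)
    grid = np.linspace(0, 4000, 2001)
    curve = np.asarray(trap(0, 0, 150, 500, left_shoulder=True).degree(grid))
    assert defuzzify_cog(curve, grid) == pytest.approx(oracle, abs=0.5)


@given(
    pts=st.lists(st.floats(0, 100, allow_nan=False), min_size=4, max_size=4),
    alpha=st.floats(0.05, 1.0),
)
def test_cog_matches_closed_form_for_random_clipped_trapezoids(pts, alpha):
    a, b, c, d = sorted(pts)
    if d - a < 1.0:
        return  # near-degenerate support: nothing to integrate
    grid = np.linspace(0, 100, 2001)
    curve = implicate(alpha, trap(a, b, c, d), grid)
    oracle = piecewise_linear_centroid(
        clipped_trapezoid_nodes(a, b, c, d, alpha, 0.0, 100.0)
    )
    assert defuzzify_cog(curve, grid) == pytest.approx(oracle, abs=0.5)


@given(alpha=st.floats(0.01, 1.0), k=st.floats(0.01, 1.0))
def test_cog_invariant_under_uniform_scaling(alpha, k):
    grid = np.linspace(0, 50, 2001)
    curve = implicate(alpha, trap(5, 10, 20, 40), grid)
    assert defuzzify_cog(k * curve, grid) == pytest.approx(
        defuzzify_cog(curve, grid)
    )


def test_cog_refinement_error_shrinks():
    """Halving the grid step never worsens the closed-form agreement."""
    a, b, c, d, alpha = 3.0, 11.0, 27.0, 61.0, 0.73
    oracle = piecewise_linear_centroid(
        clipped_trapezoid_nodes(a, b, c, d, alpha, 0.0, 100.0)
    )
    prev_err = 0.5
    for resolution in (251, 501, 1001, 2001):
        grid = np.linspace(0, 100, resolution)
        err = abs(defuzzify_cog(implicate(alpha, trap(a, b, c, d), grid), grid)
                  - oracle)
        assert err <= prev_err + 1e-12
        prev_err = err


def test_cog_of_zero_curve_raises():
    grid = np.linspace(0, 1, 101)
    with pytest.raises(ValueError):
        defuzzify_cog(np.zeros_like(grid), grid)


# --- end-to-end inference ---------------------------------------------------

def single_rule_fis(consequent_mf):
    inp = LinguisticVariable("x", (0, 10), {"on": tri(4, 5, 6), "off": trap(0, 0, 3, 5, left_shoulder=True)})
    out = LinguisticVariable("y", (0, 100), {"t": consequent_mf})
    return FISDefinition(
        "single", (inp,), out, (FuzzyRule((("x", "on"),), "t"),)
    )


def test_single_rule_limit_equals_consequent_centroid(centroid_oracle):
    """A lone rule firing at alpha=1 defuzzifies to its consequent centroid."""
    mf = trap(10, 30, 50, 90)
    fis = single_rule_fis(mf)
    result = infer(fis, {"x": 5.0})  # prototype point: alpha = 1
    assert result.firing == (1.0,)
    oracle = centroid_oracle([(10, 0.0), (30, 1.0), (50, 1.0), (90, 0.0)])
    assert result.crisp == pytest.approx(oracle, abs=0.5)


def test_infer_is_pure_and_deterministic(protfis):
    r1 = infer(protfis, {"glycaemia": 104.0, "sirolimus": 9.3})
    r2 = infer(protfis, {"glycaemia": 104.0, "sirolimus": 9.3})
    assert r1.crisp == r2.crisp
    assert r1.firing == r2.firing
    np.testing.assert_array_equal(r1.curve, r2.curve)


def test_infer_crisp_value_lies_inside_aggregate_support(protfis):
    result = infer(protfis, {"glycaemia": 95.0, "sirolimus": 6.5})
    support = result.grid[result.curve > 0]
    assert support[0] <= result.crisp <= support[-1]
    assert np.all((result.curve >= 0) & (result.curve <= 1))


def test_infer_missing_input_raises(protfis):
    with pytest.raises(ValueError, match="missing input"):
        infer(protfis, {"glycaemia": 90.0})


def test_no_rule_fired_raises_with_diagnostics(protfis):
    """Diabetic glycaemia with in-window sirolimus is a rule-base gap."""
    with pytest.raises(NoRuleFired) as excinfo:
        infer(protfis, {"glycaemia": 200.0, "sirolimus": 9.0})
    assert excinfo.value.fuzzified["glycaemia"]["danger"] == 1.0
    assert "danger" in str(excinfo.value)


def test_nearest_band_fallback_policy():
    from dataclasses import replace

    from renalfis import build_system

    fallback = replace(build_system("protfis"), no_fire_policy="nearest")
    result = infer(fallback, {"glycaemia": 200.0, "sirolimus": 9.0})
    assert np.isfinite(result.crisp)
    assert result.fired_count == 0


# --- trace report -----------------------------------------------------------

def test_trace_report_one_row_per_rule(protfis):
    result = infer(protfis, {"glycaemia": 90.0, "sirolimus": 7.82})
    report = trace_report(result, protfis)
    lines = report.splitlines()
    rule_rows = [l for l in lines if l.strip() and l.split()[0].isdigit()]
    assert len(rule_rows) == len(protfis.rules) == 8
    assert f"{result.crisp:.2f}" in lines[-1]
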