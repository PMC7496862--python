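import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from renalfis import build_system

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def protfis():
    return build_system("protfis")


@pytest.fixture(scope="session")
def gfrfis():
    return build_system("gfrfis")


@pytest.fixture(scope="session")
def protace():
    return build_system("protace")


@pytest.fixture(scope="session")
def gfrace():
    return build_system("gfrace")


@pytest.fixture(scope="session")
def all_systems(protfis, gfrfis, protace, gfrace):
    return {"protfis": protfis, "gfrfis": gfrfis,
            "protace": protace, "gfrace": gfrace}


def piecewise_linear_centroid(nodes):
    """Closed-form centroid of a piecewise-linear membership curve.

    ``nodes`` is a sequence of (x, mu) vertices with non-decreasing x.
    Integrates x*mu and mu exactly segment by segment (independent
    oracle for the discrete centre-of-gravity defuzzifier).
    """
    num = 0.0
    den = 0.0
    for (x0, y0), (x1, y1) in zip(nodes, nodes[1:]):
        dx = x1 - x0
        if dx <= 0:
            continue
        dy = y1 - y0
        den += (y0 + y1) / 2.0 * dx
        num += dx * (x0 * y0 + (x0 * dy + dx * y0) / 2.0 + dx * dy / 3.0)
    if den == 0:
        raise ValueError("curve has zero area")
    return num / den


@pytest.fixture(scope="session")
def centroid_oracle():
    return piecewise_linear_centroid


def clipped_trapezoid_nodes(a, b, c, d, alpha, lo, hi):
    """Vertex list of a trapezoid (a,b,c,d) clipped at height alpha,
    embedded in the universe [lo, hi] (zero outside the support)."""
    nodes = [(lo, 0.0)]
    if a > lo:
        nodes.append((a, 0.0))
    if b > a:
        nodes.append((a + alpha * (b - a), alpha))
    else:
        nodes.append((a, alpha))
    if d > c:
        nodes.append((d - alpha * (d - c), alpha))
    else:
        nodes.append((d, alpha))
    if d < hi:
        nodes.append((d, 0.0))
    nodes.append((hi, 0.0))
    return nodes
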