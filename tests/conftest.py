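"""Shared fixtures.

The 4x4 micropillar benchmark solve is expensive, so it is computed once
per session (at a mesh resolution that keeps the whole suite fast) and
shared by the solver, postprocess and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import asamesh as am
from asamesh.geometry import PillarLayout


@pytest.fixture(scope="session")
def material():
    return am.MaterialParams()  # E = 1.9, nu = 0.3, beta = 2, active_pressure


@pytest.fixture(scope="session")
def layout_4x4():
    return am.build_square_layout(4, 4, 400.0, 200.0)


@pytest.fixture(scope="session")
def free_square():
    """Pillar-free 1000 um square with traction-free boundary."""
    return PillarLayout(centers=np.zeros((0, 2)), radius=200.0, height=200.0,
                        substrate_bounds=(0.0, 0.0, 1000.0, 1000.0))


@pytest.fixture(scope="session")
def benchmark_4x4(layout_4x4, material):
    """Solved 4x4 contraction ramp (element size 50 um, 20 eta steps)."""
    domain = am.triangulate_domain(layout_4x4, 50.0)
    states = am.solve_contraction(domain, layout_4x4, material)
    return layout_4x4, domain, states


@pytest.fixture(scope="session")
def free_square_solved(free_square, material):
    """Pillar-free square solved to full activation (element size r/5)."""
    domain = am.triangulate_domain(free_square, 40.0)
    states = am.solve_contraction(domain, free_square, material,
                                  am.ActivationSchedule.uniform(1.0, 10))
    return domain, states
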