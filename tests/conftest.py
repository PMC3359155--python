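"""Shared fixtures: frozen configurations, fits and reference solves.

Session scope keeps the expensive artifacts (inversion fit, long
integrations) shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

import cpebswitch as cs


@pytest.fixture(scope="session")
def frozen():
    return cs.frozen_reference()


@pytest.fixture(scope="session")
def cond1(frozen):
    return cs.make_condition("I", frozen)


@pytest.fixture(scope="session")
def cond2(frozen):
    return cs.make_condition("II", frozen)


@pytest.fixture(scope="session")
def fit1(cond1):
    return cs.fit_inversion(cond1)


@pytest.fixture(scope="session")
def quartic_fps1(cond1):
    return cs.solve_fixed_points(cond1, "quartic")


@pytest.fixture(scope="session")
def protocol(frozen):
    return cs.make_stimulus(frozen=frozen)


# ---------------------------------------------------------------------------
# Independent stoichiometric oracle for the full mass-action model.
# Species order: X, XP, YP, C1, C2, C3, plus explicit free CPEB1 (Y) as a
# seventh species so conservation can be checked rather than imposed.
# ---------------------------------------------------------------------------

def oracle_fluxes(y7, p, U):
    """(stoichiometry, rates) of the six reactions, tabulated independently."""
    X, XP, YP, C1, C2, C3, Y = y7
    reactions = [
        # stoich over (X, XP, YP, C1, C2, C3, Y), rate
        ((-1, +1, 0, 0, 0, 0, 0), p.k10 * X * U),      # X + Ca4CaM -> XP
        ((+1, -1, 0, 0, 0, 0, 0), p.k1010 * XP),       # XP -> X
        ((-1, -1, 0, +1, 0, 0, 0), p.k1 * X * XP),     # X + XP -> C1
        ((+1, +1, 0, -1, 0, 0, 0), p.k2 * C1),         # C1 -> X + XP
        ((0, +2, 0, -1, 0, 0, 0), p.k3 * C1),          # C1 -> 2 XP
        ((+1, -1, 0, 0, 0, 0, 0), p.k4 * XP * p.P),    # XP + P -> X + P
        ((0, -1, 0, 0, +1, 0, -1), p.k5 * Y * XP),     # Y + XP -> C2
        ((0, +1, 0, 0, -1, 0, +1), p.k55 * C2),        # C2 -> Y + XP
        ((0, +1, +1, 0, -1, 0, 0), p.k6 * C2),         # C2 -> YP + XP
        ((0, 0, -1, 0, 0, 0, +1), p.k7 * YP * p.P),    # YP + P -> Y + P
        ((0, 0, -1, 0, 0, +1, 0), p.k8 * YP * p.T),    # YP + T -> C3
        ((0, 0, +1, 0, 0, -1, 0), p.k88 * C3),         # C3 -> YP + T
        ((+1, 0, +1, 0, 0, -1, 0), p.k9 * C3),         # C3 -> YP + X + T
    ]
    return reactions


def oracle_rhs7(y7, p, U):
    """Flux-summation derivative of the 7-species (explicit-Y) system."""
    dy = np.zeros(7)
    for stoich, rate in oracle_fluxes(y7, p, U):
        dy += np.asarray(stoich, dtype=float) * rate
    dy[0] += -p.lambda2 * (y7[0] - p.Xbasal)
    dy[1] += -p.lambda1 * (y7[1] - p.XPbasal)
    return dy


@pytest.fixture(scope="session")
def oracle():
    return oracle_rhs7
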