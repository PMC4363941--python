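"""Shared fixtures: species tables, hand-built filament states, and the
scaled-down study scenarios used by the slower simulation tests."""

from __future__ import annotations

import numpy as np
import pytest

from actinsim.core import Model
from actinsim.engine import EngineParams, SimulationState
from actinsim.model import DefaultConstants, ModelParams, make_species
from actinsim.space import SpaceModel, place_bound


@pytest.fixture(scope="session")
def constants():
    return DefaultConstants()


@pytest.fixture(scope="session")
def species(constants):
    return make_species(constants)


def bare_state(species, collision=(), timed=(), transfer=(), space=None,
               seed=0, sampler=None, k=1.0):
    """A SimulationState over hand-picked rules, for constructed fixtures."""
    model = Model(species, collision, timed, transfer,
                  orientation_sampler=sampler)
    if space is None:
        space = SpaceModel(20.0, 20.0)
    return SimulationState(model, space, EngineParams(seed=seed, k=k),
                           np.random.default_rng(seed))


def build_filament(state, x, y, angle_deg, n_actin, focal="yes"):
    """Nucleating integrin plus ``n_actin`` collinear actins at ``angle_deg``.

    Returns (integrin, [actin1..actinN]) with actin1 bound to the integrin's
    site by its pointed end and growth toward the barbed end.
    """
    integ = state.add_particle("integrin", x, y, {"focal": focal})
    integ.orient = angle_deg % 360.0
    prev, prev_site = integ, "fa"
    actins = []
    for _ in range(n_actin):
        px, py, orient = place_bound(prev, prev_site,
                                     state.model.species["actin"], "pointed")
        a = state.add_particle("actin", px, py)
        a.orient = orient
        state.bind(prev, prev_site, a, "pointed")
        prev, prev_site = a, "barbed"
        actins.append(a)
    return integ, actins


# ---------------------------------------------------------------------------
# Scaled-down study scenarios.  The full study conditions (27.5 μm domain,
# 250/400/100 particles, t=48) are kept as the package defaults; the test
# suite exercises the same model on geometrically similar miniatures — the
# pillar share is identical (29.7%) and particle densities are preserved —
# with a coarser engine step (k=2) and shorter horizon.

def half_scale_params(**over) -> ModelParams:
    """Half-linear-scale layout (13.75 μm domain, pillars 2.5/5 μm),
    amounts scaled by area (1/4)."""
    base = dict(nActin=63, nCofilin=100, nIntegrin=25,
                pillar_width=2.5, pitch=5.0, n_grid=3, tEnd=12.0)
    base.update(over)
    return ModelParams(**base)


def quarter_scale_params(**over) -> ModelParams:
    """Quarter-linear-scale layout (6.875 μm domain), amounts by area (1/16)."""
    base = dict(nActin=16, nCofilin=25, nIntegrin=6,
                pillar_width=1.25, pitch=2.5, n_grid=3, tEnd=12.0)
    base.update(over)
    return ModelParams(**base)


def fast_engine(seed: int) -> EngineParams:
    return EngineParams(k=2.0, seed=seed)
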