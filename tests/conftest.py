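"""Shared fixtures.

The treatment simulations used by several acceptance checks are expensive
relative to the unit tests, so they are computed once per session and
shared. All pipelines are deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

import scleraxl as sx
from scleraxl.mesh import Mesh


@pytest.fixture(scope="session")
def consts():
    return sx.load_shared_constants()


@pytest.fixture(scope="session")
def rat_params():
    return sx.load_species_params("rat")


@pytest.fixture(scope="session")
def all_params():
    return {s: sx.load_species_params(s) for s in sx.SPECIES_IDS}


@pytest.fixture(scope="session")
def baseline_results(all_params):
    """Full 30-min baseline treatment runs (21% O2, 424 mW/cm², 3 mM MB)."""
    return {s: sx.simulate(p) for s, p in all_params.items()}


@pytest.fixture(scope="session")
def rat_optimum_result(rat_params):
    """Rat run at the reported optimal treatment (30 mM, 1000 mW/cm², 300%)."""
    cond = sx.TreatmentConditions(fluence=1000.0, mb_injected_mm=30.0,
                                  pct_inspired_o2=300.0)
    return sx.simulate(rat_params, cond)


def uniform_mesh(n: int, length_um: float, layer: str = "sclera") -> Mesh:
    """Single-layer uniform mesh used by transport/optics unit tests."""
    dx_um = length_um / n
    lengths = {"choroid": 0.0, "sclera": 0.0, "tenon": 0.0, "reservoir": 0.0}
    lengths[layer] = length_um
    return Mesh(
        layer=np.array([layer] * n),
        thickness_cm=np.full(n, dx_um / 1e4),
        center_um=(np.arange(n) + 0.5) * dx_um,
        counts={layer: n},
        layer_lengths_um=lengths,
    )
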