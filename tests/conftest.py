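"""Shared fixtures: small meshes, calibrated material, session-scoped runs."""

import numpy as np
import pytest

from ctcsim import membrane_mechanics as mm
from ctcsim.presets import CTC_MATERIAL


@pytest.fixture(scope="session")
def sphere42():
    return mm.build_icosphere_mesh(2.0, 42)


@pytest.fixture(scope="session")
def sphere162():
    return mm.build_icosphere_mesh(8.0, 162)


@pytest.fixture(scope="session")
def sphere642():
    return mm.build_icosphere_mesh(8.0, 642)


@pytest.fixture(scope="session")
def ctc_material():
    return mm.MaterialModel(**CTC_MATERIAL)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def stretch_curves(ctc_material):
    """Calibrated quasi-static stretch curves for 8 and 12 um tumor cells."""
    out = {}
    for d in (8.0, 12.0):
        mesh = mm.build_icosphere_mesh(d, 642)
        out[d] = mm.stretch_test(
            mesh, ctc_material, max_force=2000.0, n_levels=10,
            solver_opts={"residual_tol": 0.2},
        )
    return out
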