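"""Shared fixtures: study-condition protocols and reusable synthetic data."""

import numpy as np
import pytest

from calixtherm import synthgen
from calixtherm.itcfit import ITCExperiment


@pytest.fixture(scope="session")
def uv_protocol():
    """Direct UV titration schedule at the study's cuvette conditions."""
    return synthgen.default_uv_protocol()


@pytest.fixture(scope="session")
def competitive_protocol():
    """Competitive UV schedule: ligand + Na in the cell, cation titrant."""
    return synthgen.default_uv_protocol(
        c_ligand=1.10e-4, c_titrant=1.6e-3, max_ratio=3, n_points=18,
        extra_cell={"Na": 1.10e-4},
    )


def itc_shell(c_ligand=1.15e-4, c_titrant=1.32e-3, n_inj=25, inj_mm3=12.0, v0=1.42):
    """Empty ITC experiment (heats zero) with the study's cell geometry."""
    return ITCExperiment(
        cell_volume=v0,
        injection_volumes=np.full(n_inj, inj_mm3),
        heats=np.zeros(n_inj),
        cell_conc={"L": c_ligand},
        syringe_conc={"M": c_titrant},
    )


@pytest.fixture(scope="session")
def calibration_itc():
    """Noiseless thermogram at the instrument-calibration parameters
    (18-crown-6 + Ba2+: K = 5772 dm3 mol-1, dH = -32.2 kJ mol-1)."""
    from calixtherm import itcfit

    model = synthgen.make_1to1_model(np.log10(5772.0))
    shell = ITCExperiment(
        cell_volume=1.42,
        injection_volumes=np.full(25, 12.0),
        heats=np.zeros(25),
        cell_conc={"L": 1.7e-3},
        syringe_conc={"M": 3.4e-2},
    )
    return itcfit.simulate_itc(model, shell, {"ML": -32.2})
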