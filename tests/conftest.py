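import numpy as np
import pytest

from episem.dynamics import IntegratorConfig
from episem.io import SimConfig
from episem.mechanics import default_phase_params
from episem.tissue import initialize_tissue


@pytest.fixture(scope="session")
def params():
    return default_phase_params()


@pytest.fixture(scope="session")
def coarse_cfg():
    """Desk-scale configuration used by most tissue-level tests."""
    from episem.io import suggested_dt

    return SimConfig(resolution=0.2,
                     integrator=IntegratorConfig(dt=suggested_dt(0.2)))


@pytest.fixture(scope="session")
def full_cfg():
    return SimConfig()


def relax(ts, cfg, duration):
    from episem import dynamics as dyn

    for _ in range(int(round(duration / cfg.integrator.dt))):
        f, _ = dyn.net_forces_and_virial(ts)
        dyn.euler_step(ts, f, cfg.integrator)
    return ts


@pytest.fixture(scope="session")
def relaxed_single_cell(full_cfg):
    """A full-resolution cell relaxed to mechanical equilibrium."""
    ts = initialize_tissue(1, full_cfg, seed=7)
    return relax(ts, full_cfg, 120.0)


@pytest.fixture(scope="session")
def relaxed_pair(coarse_cfg):
    """Two coarse cells relaxed into adhesive contact."""
    from dataclasses import replace

    cfg = replace(coarse_cfg, initial_gap=0.25)
    ts = initialize_tissue(2, cfg, seed=3)
    return relax(ts, cfg, 60.0), cfg


@pytest.fixture(scope="session")
def small_cluster(coarse_cfg):
    """Seven coarse cells relaxed into a sheet (no growth applied)."""
    ts = initialize_tissue(7, coarse_cfg, seed=11)
    return relax(ts, coarse_cfg, 90.0)
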