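import numpy as np
import pytest

import torsemide_pbpk as tp


@pytest.fixture(scope="session")
def healthy():
    return tp.healthy_reference()


@pytest.fixture(scope="session")
def traj_10mg_oral(healthy):
    """Single 10 mg oral dose in the healthy reference adult, 48 h."""
    phys, drug = healthy
    spec = tp.single_dose_spec(phys, drug, 10.0, route="oral",
                               t_end=48.0, n_points=481)
    return tp.simulate(spec)


@pytest.fixture(scope="session")
def traj_10mg_oral_pd(traj_10mg_oral):
    traj = tp.Trajectory(times=traj_10mg_oral.times,
                         amounts=traj_10mg_oral.amounts,
                         C_plasma=traj_10mg_oral.C_plasma,
                         x=traj_10mg_oral.x,
                         dosed=traj_10mg_oral.dosed)
    return tp.pd_timecourse(traj, tp.PD_PRESETS["healthy"])
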