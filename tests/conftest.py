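import numpy as np
import pytest

from mlmm.dynamics import SimulationPlan, minimize_frame, run_simulation
from mlmm.synthetic_fixtures import (
    combine_solute_bath,
    make_solvent_bath,
    make_toy_solute,
)


@pytest.fixture(scope="session")
def ti_system():
    """Small solvated system for free-energy tests: 4-atom flexible solute in
    a 12-molecule triatomic bath, energy-minimized."""
    solute, _, sframe = make_toy_solute(4, seed=21)
    bath, bframe = make_solvent_bath(12, 10.0, seed=21, cavity_radius=3.5)
    system, frame = combine_solute_bath(solute, sframe, bath, bframe)
    return system, minimize_frame(system, frame, maxiter=500)


@pytest.fixture(scope="session")
def rigid_ti_system():
    """Same composition but with a rigid solute (frozen internal geometry)."""
    solute, _, sframe = make_toy_solute(4, flexible=False, seed=21)
    bath, bframe = make_solvent_bath(12, 10.0, seed=21, cavity_radius=3.5)
    system, frame = combine_solute_bath(solute, sframe, bath, bframe)
    return system, minimize_frame(system, frame, maxiter=300)


@pytest.fixture(scope="session")
def nve_system():
    """Conservation test bed: 6-atom solute + 30-molecule bath, minimized and
    pre-equilibrated with a short 10 K NVE roll so the measured run starts
    from a typical (not special) configuration."""
    solute, _, sframe = make_toy_solute(6, seed=11)
    bath, bframe = make_solvent_bath(30, 12.5, seed=11, cavity_radius=4.0)
    system, frame = combine_solute_bath(solute, sframe, bath, bframe)
    frame = minimize_frame(system, frame, maxiter=1000)
    pre = SimulationPlan(ensemble="NVE", dt=0.5, n_steps=1000,
                         report_interval=1000, seed=3, init_temperature=10.0)
    traj, _ = run_simulation(system, frame, pre)
    return system, traj[-1]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
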