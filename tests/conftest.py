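import numpy as np
import pytest

from petkin.models import make_basis
from petkin.simulate import (
    SimulationSpec,
    blank_gap,
    frame_average,
    simulate_tacs,
    simulate_target,
)
from petkin.tac import TAC


@pytest.fixture(scope="session")
def spec0():
    """Default study conditions without noise."""
    return SimulationSpec(noise_scale=0.0)


@pytest.fixture(scope="session")
def noiseless(spec0):
    """Noiseless reference + 11 regional target TACs with ground truth."""
    return simulate_tacs(spec0)


@pytest.fixture(scope="session")
def truth_curve(noiseless):
    return noiseless.ref_curve


@pytest.fixture(scope="session")
def schedule(spec0):
    return spec0.schedule


@pytest.fixture(scope="session")
def fine_basis(truth_curve, schedule):
    """Dense basis on the simulation grid, bracketing every true k2a."""
    return make_basis(truth_curve, schedule, n_basis=256, k2a_range=(0.01, 1.0), step=0.01)


@pytest.fixture(scope="session")
def default_basis(truth_curve, schedule):
    return make_basis(truth_curve, schedule)


def make_panel(truth_curve, schedule, n=30, step=0.01):
    """Noiseless SRTM TACs spanning BP_ND in [0, 2] with mixed R1/k2."""
    t = np.union1d(
        np.concatenate(
            [np.arange(0.0, schedule.end_min[-1], step), schedule.start_min,
             schedule.end_min, schedule.midtimes_min]
        ),
        [0.0, float(schedule.end_min[-1])],
    )
    r1s = [0.8, 1.0, 1.2, 0.9, 1.1]
    k2s = [0.12, 0.18, 0.15]
    panel = []
    for i, bp in enumerate(np.linspace(0.0, 2.0, n)):
        r1 = r1s[i % len(r1s)]
        k2 = k2s[i % len(k2s)]
        vals = simulate_target(truth_curve, r1, k2, bp, t, step)
        panel.append((frame_average(t, vals, schedule), dict(r1=r1, k2=k2, bp_nd=float(bp))))
    return panel


@pytest.fixture(scope="session")
def bp_panel(truth_curve, schedule):
    return make_panel(truth_curve, schedule)


@pytest.fixture(scope="session")
def gapped_ref(noiseless):
    """Dual-time-window reference TAC: 30-90 min frames removed."""
    return blank_gap(noiseless.noiseless_ref)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def identity_tac(noiseless) -> TAC:
    """A TAC equal to the frame-averaged reference curve (C_T == C_R)."""
    return noiseless.noiseless_ref
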