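import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from tsmr import (  # noqa: E402
    HarmonizedInstrument,
    InstrumentSet,
    SimScenario,
    harmonize_tables,
    make_worked_fixture,
    simulate_two_sample,
)


def make_h(
    vid="v1",
    bx=0.1,
    sx=0.004,
    by=0.02,
    sy=0.02,
    ea="A",
    oa="G",
    eaf_x=0.3,
    eaf_y=0.3,
    action="none",
):
    return HarmonizedInstrument(vid, ea, oa, bx, sx, by, sy, eaf_x, eaf_y, action)


def make_harmonized(bx, by, sy, sx=None):
    """Build a list of harmonized instruments from effect/SE arrays."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.broadcast_to(np.asarray(sy, dtype=float), bx.shape)
    sx = np.broadcast_to(np.asarray(0.004 if sx is None else sx, dtype=float), bx.shape)
    return [
        make_h(vid=f"v{i + 1}", bx=float(bx[i]), sx=float(sx[i]), by=float(by[i]), sy=float(sy[i]))
        for i in range(len(bx))
    ]


def sim_harmonized(scn: SimScenario):
    """Simulate a scenario and harmonize its own exposure/outcome pair."""
    sim = simulate_two_sample(scn)
    iset = InstrumentSet(sim.exposure.trait_label, list(sim.exposure.records))
    return harmonize_tables(iset, sim.outcome).instruments, sim


@pytest.fixture
def worked():
    return make_worked_fixture()
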