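import numpy as np
import pytest

from cantibeat import synthetic as syn
from cantibeat.beam_core import silver_wire
from cantibeat.spectral import DisplacementTrace


@pytest.fixture(scope="session")
def stiff_spec():
    """Default probe: 0.2 mm silver wire, 10 mm working length."""
    return silver_wire()


@pytest.fixture(scope="session")
def compliant_spec():
    """100 mm silver wire whose first natural frequency (~7.9 Hz) sits in
    the beating band — exercises the non-quasi-static regime."""
    return syn.compliant_wire()


def simulate_twitch_displacement(
    params,
    spec,
    record_beats=10,
    settle_beats=4,
    dt=2.5e-4,
    output_fs=60.0,
):
    """Forward-simulate a twitch train and return the steady-state window
    of the tip displacement (starting at a beat boundary)."""
    total = (record_beats + settle_beats) * params.period
    tgrid = np.arange(0.0, total + dt, dt)
    force = syn.twitch_force(params, tgrid, ramp_beats=2)
    sim = syn.simulate_cantilever_fd(
        force, spec, syn.BeamSimConfig(dt=dt, output_fs=output_fs)
    )
    mask = sim.times >= settle_beats * params.period - 1e-9
    return DisplacementTrace(
        sim.times[mask] - sim.times[mask][0], sim.values[mask]
    )


@pytest.fixture(scope="session")
def ventricular_sim(stiff_spec):
    """Steady-state 20-beat ventricular displacement record at 60 fps,
    with its generating parameters and generator-truth metrics."""
    params = syn.ventricular_preset()
    trace = simulate_twitch_displacement(params, stiff_spec, record_beats=20)
    return params, trace, syn.twitch_truth_metrics(params)


@pytest.fixture(scope="session")
def atrial_sim(stiff_spec):
    params = syn.atrial_preset()
    trace = simulate_twitch_displacement(params, stiff_spec, record_beats=20)
    return params, trace, syn.twitch_truth_metrics(params)
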