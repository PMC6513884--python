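import pytest

import pscradle as pc


@pytest.fixture(scope="session")
def geometry():
    return pc.derive_geometry()


@pytest.fixture(scope="session")
def params():
    return pc.ModelParameters()


@pytest.fixture(scope="session")
def calibrated(geometry):
    """Calibrated parameter set + report, shared across the session."""
    return pc.calibrate_rest(pc.ModelParameters(), geometry)


@pytest.fixture(scope="session")
def stimulus_amplitudes(calibrated, geometry):
    """Pulse amplitudes calibrated per firing rate, computed once."""
    cal, _ = calibrated
    cache = {}

    def get(rate: float) -> float:
        if rate not in cache:
            cache[rate] = pc.calibrate_stimulus(rate, cal, geometry)
        return cache[rate]

    return get


@pytest.fixture(scope="session")
def protocol_runs(calibrated, geometry, stimulus_amplitudes):
    """Short stimulation protocols (2 s settle, 10 s stimulus, 5 s recovery)
    at a given rate, cached across the whole suite."""
    cal, rep = calibrated
    cache = {}

    def get(rate: float) -> pc.SimResult:
        if rate not in cache:
            cfg = pc.SimConfig(
                t_settle=2.0, t_stim=10.0, t_post=5.0,
                stimulus=pc.StimulusSpec(mode="pulse", rate=rate,
                                         amplitude=stimulus_amplitudes(rate)),
            )
            cache[rate] = pc.run_simulation(cal, geometry, cfg, calibration=rep)
        return cache[rate]

    return get


@pytest.fixture(scope="session")
def rest_run(calibrated, geometry):
    """Zero-stimulus 10 s run from the calibrated resting state."""
    cal, rep = calibrated
    cfg = pc.SimConfig(t_settle=10.0, t_stim=0.0, t_post=0.0,
                       stimulus=pc.StimulusSpec(mode="none"))
    return pc.run_simulation(cal, geometry, cfg, calibration=rep)
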