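"""Shared fixtures: default montage/paradigm and a cached noiseless
forward-simulated recording with its full-pipeline analysis (several tests
check different facets of the same run, so it is built once per session)."""

import numpy as np
import pytest

import nirsblock as nb


@pytest.fixture(scope="session")
def montage():
    return nb.default_montage()


@pytest.fixture(scope="session")
def schedule():
    return nb.default_paradigm()


@pytest.fixture(scope="session")
def noiseless_truth():
    amp = nb.default_amplitudes(40.0)
    amp.loc["rM1", "wFC"] = 50.0
    return nb.SimulationTruth(amp_hbo=amp, noise=nb.NoiseSpec.silent(),
                              motion=nb.MotionSpec.none(),
                              subject_gain_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def noiseless_recording(montage, schedule, noiseless_truth):
    return nb.simulate_recording(montage, schedule, noiseless_truth)


@pytest.fixture(scope="session")
def noiseless_analysis(noiseless_recording, schedule):
    return nb.analyze_subject(noiseless_recording, schedule)


@pytest.fixture(scope="session")
def noisy_recording(montage, schedule):
    truth = nb.SimulationTruth(seed=42)
    return nb.simulate_recording(montage, schedule, truth)
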