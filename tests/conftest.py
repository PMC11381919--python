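"""Shared fixtures: small noise-free simulated wells.

Simulation fixtures run at 2 kHz with short durations so the suite stays
fast; accuracy-critical checks raise the rate themselves.
"""

import pytest

from meafp import assemble_feature_table, simulate_recording
from meafp.simulate import preset_config


@pytest.fixture(scope="session")
def wt_clean_bundle():
    """Noise-free wild-type well: 2 kHz, 20 s (~20 beats)."""
    return simulate_recording(preset_config("wt", sampling_rate=2000.0,
                                            duration=20.0, noise_sd=0.0, seed=11))


@pytest.fixture(scope="session")
def wt_clean_features(wt_clean_bundle):
    return assemble_feature_table([wt_clean_bundle])


@pytest.fixture(scope="session")
def r403q_clean_bundle():
    """Noise-free mutant well with ectopy: 2 kHz, 120 s."""
    return simulate_recording(preset_config("r403q", sampling_rate=2000.0,
                                            duration=120.0, noise_sd=0.0, seed=2))


@pytest.fixture(scope="session")
def r403q_clean_features(r403q_clean_bundle):
    return assemble_feature_table([r403q_clean_bundle])
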