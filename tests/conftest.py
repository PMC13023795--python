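import numpy as np
import pytest

import ecgmi


@pytest.fixture(scope="session")
def ecg_segment():
    """One preprocessed (denoised, normalized) 10,000-sample MI segment."""
    rec = ecgmi.generate_record(ecgmi.SynthConfig.for_class("MI", duration=12.0, seed=11))
    return ecgmi.preprocess_records([rec])[0]


@pytest.fixture(scope="session")
def component_set(ecg_segment):
    return ecgmi.build_component_set(ecg_segment)


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test (keeps tests order-independent)."""
    return np.random.default_rng(20240917)
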