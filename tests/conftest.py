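import numpy as np
import pytest

from fpevent import (BinSpec, SegmentationSpec, SyntheticConfig,
                     baseline_correct, extract_events, generate_corpus,
                     segment_recording)

SEED = 7


@pytest.fixture(scope="session")
def small_config():
    """2 blocks x 10 trials: enough structure, fast to generate."""
    return SyntheticConfig(n_blocks=2, n_trials_per_block=10)


@pytest.fixture(scope="session")
def small_corpus(small_config):
    return generate_corpus(small_config, SEED)


@pytest.fixture(scope="session")
def seg_spec():
    return SegmentationSpec()


@pytest.fixture(scope="session")
def bin_spec():
    return BinSpec()


@pytest.fixture(scope="session")
def small_segments(small_corpus, seg_spec):
    """All trials of the small corpus, segmented and baseline-corrected."""
    recordings, _ = small_corpus
    segments = []
    for rec in recordings:
        events = extract_events(rec.trigger_codes, rec.sampling_rate)
        for seg in segment_recording(rec, events, seg_spec):
            segments.append(baseline_correct(seg, seg_spec, ["Mx", "My"]))
    return segments


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
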