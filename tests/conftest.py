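"""Shared fixtures.

Heavy pipeline artifacts (the default synthetic cohort, its cross-validated
decoder, the novelty suite) are session-scoped so the acceptance tests
share one computation.  Unit tests use short recordings with a compressed
event timeline.
"""

import time

import numpy as np
import pytest

from cardioloop import synth, features, decode, novelty, workbench

MASTER_SEED = 11


def short_protocol(agent="D+NE", end=64.0, dose_scale=1.0):
    """Compressed timeline for fast unit tests: 10 s background,
    infusion at 24 s, 64 s recording."""
    return synth.InfusionProtocol(
        agent=agent, dose_scale=dose_scale,
        timeline={"stream_start": 0.0, "window_init": 4.0, "decode_start": 14.0,
                  "infusion_start": 24.0, "end": 64.0},
        onset_lag=5.0, ramp_width=6.0)


@pytest.fixture(scope="session")
def noiseless_subject():
    return synth.draw_subject(np.random.default_rng(3), seed=42).noiseless()


@pytest.fixture(scope="session")
def noiseless_record(noiseless_subject):
    """Full-timeline noiseless D+NE recording (the closure oracle)."""
    return synth.generate_recording(
        synth.InfusionProtocol(agent="D+NE"), noiseless_subject)


@pytest.fixture(scope="session")
def noiseless_frame(noiseless_record):
    return features.extract_features(noiseless_record)


@pytest.fixture(scope="session")
def short_record():
    subject = synth.draw_subject(np.random.default_rng(5), seed=77)
    return synth.generate_recording(short_protocol(), subject)


@pytest.fixture(scope="session")
def default_cohort_dataset():
    """The default decoding cohort: 5 subjects x 6 recordings
    (2 each of D, NE, D+NE), standard dose, full timeline."""
    return workbench.cohort_dataset(
        5, ["D", "D", "NE", "NE", "D+NE", "D+NE"], seed=MASTER_SEED)


@pytest.fixture(scope="session")
def highdose_dataset():
    """Emerging-state recordings: 4 subjects x (H-D, H-NE, H-D+NE)."""
    return workbench.cohort_dataset(
        4, ["H-D", "H-NE", "H-D+NE"], seed=MASTER_SEED + 1)


@pytest.fixture(scope="session")
def decoder_cv_report(default_cohort_dataset):
    """10-fold cross-validation of the decoder on the default cohort
    (returns the report plus the wall time it took)."""
    t0 = time.time()
    report = decode.crossvalidate(
        default_cohort_dataset, decode.DecoderConfig(seed=MASTER_SEED),
        k=10, seed=MASTER_SEED)
    return report, time.time() - t0


@pytest.fixture(scope="session")
def trained_decoder(default_cohort_dataset):
    """A decoder trained on the full default cohort (for closed-loop use)."""
    return decode.train(default_cohort_dataset,
                        decode.DecoderConfig(seed=MASTER_SEED))


@pytest.fixture(scope="session")
def novelty_suite(default_cohort_dataset, highdose_dataset):
    """The cross-validated emerging-state suite (all three detectors);
    returns the result bundle plus the wall time it took."""
    t0 = time.time()
    suite = novelty.run_novelty_suite(
        default_cohort_dataset, highdose_dataset,
        novelty.NoveltyConfig(seed=MASTER_SEED), k=10, seed=MASTER_SEED)
    return suite, time.time() - t0


@pytest.fixture(scope="session")
def tiny_sequence_set():
    """Small separable 4-class sequence set for decoder unit tests."""
    rng = np.random.default_rng(9)
    seqs, labs, states = [], [], []
    for rec in range(12):
        c = rec % 4
        T = 300
        z = rng.normal(0, 0.4, size=(T, 13)).astype(np.float32)
        y = np.zeros(T, dtype=int)
        if c > 0:
            z[T // 2:, c] += 3.0
            y[T // 2:] = c
        seqs.append(z)
        labs.append(y)
        states.append(decode.CLASSES[c] if c > 0 else "rest")
    return decode.LabeledSequenceSet(seqs, labs, states, list(range(12)))
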