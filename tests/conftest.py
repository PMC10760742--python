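import numpy as np
import pytest

from fixent import GazeRecording


@pytest.fixture
def random_recording():
    """A small irregular-ish but valid recording with mixed labels."""
    rng = np.random.default_rng(42)
    n = 120
    t = 4.0 * np.arange(n)
    x = rng.normal(0, 0.5, n).cumsum() * 0.01
    labels = np.concatenate([
        np.full(30, 2), np.full(45, 1), np.full(30, 2), np.full(15, 3),
    ])
    return GazeRecording(t, x, labels, sample_rate_hz=250.0, dataset_id="fixture")


def random_sequences(n_seq, seed, n_lo=12, n_hi=80):
    """Seeded random test sequences of mixed lengths and scales."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_seq):
        n = int(rng.integers(n_lo, n_hi + 1))
        scale = float(rng.choice([0.02, 0.3, 5.0]))
        base = rng.normal(0, scale, n)
        if rng.random() < 0.3:  # add structure so matches exist at many r
            base += scale * np.sin(2 * np.pi * np.arange(n) / rng.uniform(5, 20))
        out.append(base)
    return out
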