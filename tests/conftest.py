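import numpy as np
import pytest

from ppgsas.nn import ModelSpec, TrainConfig
from ppgsas.segments import standardize


@pytest.fixture(scope="session")
def small_spec():
    """A scaled-down architecture preserving the 8-conv/4-pool/2-LSTM/2-FC shape."""
    return ModelSpec(input_length=256,
                     conv_groups=((2, 8), (2, 8), (2, 16), (2, 16)),
                     lstm_hidden=16, fc_sizes=(16, 1))


def make_sine_noise_benchmark(n=200, length=256, seed=0):
    """Linearly trivial two-class set: pure sinusoids vs pure white noise."""
    rng = np.random.default_rng(seed)
    x = np.empty((n, length))
    y = np.empty(n, dtype=np.int64)
    t = np.arange(length)
    for i in range(n):
        if i % 2:
            freq = rng.uniform(4, 8) / length
            x[i] = np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
            y[i] = 1
        else:
            x[i] = rng.normal(size=length)
            y[i] = 0
    return standardize(x).astype(np.float32), y


@pytest.fixture(scope="session")
def sine_noise_benchmark():
    x, y = make_sine_noise_benchmark()
    return x[:140], y[:140], x[140:], y[140:]  # train / validation arrays


@pytest.fixture(scope="session")
def quick_train_config():
    return TrainConfig(max_epochs=12, early_stopping_patience=4, batch_size=32, seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """6 healthy + 6 SAS subjects, 10 min each (240 segments)."""
    import ppgsas as P
    return P.generate_cohort(6, 6, P.SynthConfig(duration_s=600), seed=11)


@pytest.fixture(scope="session")
def small_segments(small_cohort):
    import ppgsas as P
    return P.segment_cohort(small_cohort)
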