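"""Shared fixtures: small, fast synthetic recordings and trial tensors.

Heavy fixtures are session-scoped so the high-SNR run is simulated and
decomposed once; the 4×4 grid keeps runtimes low without changing any of
the statistical structure the tests probe.
"""

import numpy as np
import pytest

from artidec import (GridLayout, SimConfig, TrialTensor, gabor_power,
                     generate_run, preprocess_run)

FAST_LAYOUT = GridLayout(4, 4, 4.0)


def fast_config(**overrides) -> SimConfig:
    """4×4-grid variant of the default study design (512 Hz, 20 trials per
    class, 1.5 s cues, 1.5 s inter-trial intervals)."""
    kwargs = dict(layout=FAST_LAYOUT, seed=0)
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def make_tensor(rng, n_per_class=20, n_classes=4, n_electrodes=16, n_times=8,
                class_means=None, fs=512.0):
    """Synthetic trial tensor: unit Gaussian noise plus optional per-class
    per-electrode mean shifts (``class_means``: (n_classes, n_electrodes))."""
    labels = np.repeat([f"class_{i + 1}" for i in range(n_classes)], n_per_class)
    labels = labels[rng.permutation(len(labels))].astype(object)
    data = rng.standard_normal((len(labels), n_electrodes, n_times))
    if class_means is not None:
        class_means = np.asarray(class_means, dtype=float)
        for i in range(n_classes):
            rows = labels == f"class_{i + 1}"
            data[rows] += class_means[i][None, :, None]
    return TrialTensor(data, labels, np.arange(n_electrodes), fs,
                       smoothing_s=0.5, epoch_s=n_times / fs)


@pytest.fixture(scope="session")
def tiny_run():
    """Short run (3 trials per class) for signal-level unit tests."""
    return generate_run(fast_config(trials_per_class=3, rest_trials=3, seed=5))


@pytest.fixture(scope="session")
def hi_snr_pipeline():
    """Full high-SNR run taken through preprocess + Gabor envelope once."""
    run = generate_run(fast_config(effect_db=6.0, seed=11))
    clean, mask = preprocess_run(run)
    env = gabor_power(clean)
    return run, clean, mask, env
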