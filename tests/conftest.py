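import numpy as np
import pandas as pd
import pytest

from dovekie import synth

FS = 48_000


@pytest.fixture(scope="session")
def specs():
    return synth.default_specs()


@pytest.fixture(scope="session")
def feature_table(specs):
    """Balanced 8-type, 30-calls-per-type feature table (fixed seed)."""
    return synth.sample_feature_table(specs, n_per_type=30, seed=42)


@pytest.fixture(scope="session")
def tone():
    """0.5 s pure 700 Hz tone at 48 kHz."""
    t = np.arange(int(0.5 * FS)) / FS
    return np.sin(2 * np.pi * 700 * t)


def harmonic_stack(f0, duration=0.3, fs=FS, n_harmonics=8):
    t = np.arange(int(duration * fs)) / fs
    x = np.zeros_like(t)
    for k in range(1, n_harmonics + 1):
        if k * f0 < 0.45 * fs:
            x += np.sin(2 * np.pi * k * f0 * t) / k
    return x


def gaussian_cloud_table(n_per_class, n_classes, n_features=8, seed=0,
                         shift=0.0):
    """Labelled Gaussian clouds; ``shift`` separates class means."""
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_classes):
        X = rng.normal(size=(n_per_class, n_features)) + shift * c
        for i in range(n_per_class):
            row = {"call_id": f"c{c}_{i:03d}", "call_type": f"type{c}"}
            row.update({f"x{j}": X[i, j] for j in range(n_features)})
            rows.append(row)
    return pd.DataFrame(rows)
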