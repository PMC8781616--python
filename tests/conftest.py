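import numpy as np
import pytest

import hhtecg as hg

FS = 360.0


def tone_frame(freq_hz: float, duration_s: float = 3.0, amplitude: float = 1.0,
               fs: float = FS) -> hg.Frame:
    t = np.arange(round(duration_s * fs)) / fs
    return hg.Frame(amplitude * np.sin(2 * np.pi * freq_hz * t), fs,
                    duration_s=duration_s)


@pytest.fixture(scope="session")
def reference_model() -> hg.GaussianFeatureModel:
    return hg.reference_feature_model()


@pytest.fixture(scope="session")
def separable_features() -> list[hg.FeatureRecord]:
    """Two classes 10 pooled-sd apart in every feature: trivially learnable."""
    rng = np.random.default_rng(42)
    X = np.vstack([rng.normal(0.0, 1.0, (100, 6)), rng.normal(10.0, 1.0, (100, 6))])
    labels = [1] * 100 + [5] * 100
    return [hg.FeatureRecord(x, lab) for x, lab in zip(X, labels)]


@pytest.fixture(scope="session")
def reference_features(reference_model) -> list[hg.FeatureRecord]:
    """Balanced 5-class Gaussian draw from the reference feature table."""
    return hg.simulate_features(reference_model, 200, seed=11)
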