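import numpy as np
import pandas as pd
import pytest

from speechsev.audio_io import AudioSignal
from speechsev.features import FEATURE_COLUMNS
from speechsev.model import LabeledDataset


def make_tone(freq_hz: float, duration_s: float = 1.0, sr: int = 16000,
              amplitude: float = 0.5) -> AudioSignal:
    t = np.arange(int(duration_s * sr)) / sr
    return AudioSignal(amplitude * np.sin(2 * np.pi * freq_hz * t), sr)


@pytest.fixture
def tone():
    return make_tone


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """Six subjects, one per severity label, with short free speech."""
    from speechsev.synthetic import generate_cohort

    out = tmp_path_factory.mktemp("cohort6")
    manifest = generate_cohort(out, n_subjects=6, seed=7, one_per_label=True)
    return out, manifest


@pytest.fixture(scope="session")
def small_features(small_cohort):
    from speechsev.features import extract_from_manifest

    out, manifest = small_cohort
    return extract_from_manifest(manifest, out)


def random_dataset(n: int = 30, seed: int = 0, informative: bool = False
                   ) -> LabeledDataset:
    """A fabricated 141-column dataset; optionally label-informative."""
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 6, n)
    x = rng.standard_normal((n, len(FEATURE_COLUMNS)))
    if informative:
        x[:, 0] = labels + 0.05 * rng.standard_normal(n)
        x[:, 1] = -labels + 0.05 * rng.standard_normal(n)
    features = pd.DataFrame(x, columns=list(FEATURE_COLUMNS))
    return LabeledDataset(
        features=features,
        labels=labels,
        subject_ids=np.array([f"s{i:03d}" for i in range(n)]),
    )
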