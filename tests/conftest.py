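import numpy as np
import pytest

from eegdfc.features import ExtractorSpec
from eegdfc.pipeline import PipelineConfig, _compute_features
from eegdfc.synthetic import CorpusSpec, generate_corpus


@pytest.fixture(scope="session")
def small_spec():
    """Miniature corpus: 3 subjects x 6 trials x 4 channels, 2 informative."""
    return CorpusSpec(
        n_subjects=3,
        n_trials_per_subject=6,
        n_channels=4,
        n_classes=3,
        trial_duration=2.0,
        informative_channels=(0, 1),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_corpus(small_spec):
    return generate_corpus(small_spec)


@pytest.fixture(scope="session")
def small_tables(small_corpus):
    """Four lite-model feature tables for the miniature corpus."""
    cfg = PipelineConfig()
    specs = [ExtractorSpec(name="lite", seed=s) for s in (1, 2, 3, 4)]
    return _compute_features(small_corpus, cfg, specs)


@pytest.fixture(scope="session")
def small_table(small_tables):
    return small_tables[0]


def random_feature_table(rng, n_obs=12, n_channels=2, label_of=None):
    """A FeatureTable of random rows keyed over (subject, trial, channel)."""
    from eegdfc.features import FeatureTable

    keys, rows = [], []
    i = 0
    for trial in range(n_obs // n_channels):
        label = label_of(trial) if label_of else trial % 2
        for ch in range(n_channels):
            keys.append((0, trial, f"ch{ch}", "m0", label))
            rows.append(rng.normal(size=1000))
            i += 1
    return FeatureTable(rows=np.asarray(rows), keys=keys)
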