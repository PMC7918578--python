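import numpy as np
import pytest

from surgspeech.corpus import table2_fixture
from surgspeech.synthetic import SyntheticConfig, corpus_from_counts, generate_corpus


@pytest.fixture(scope="session")
def separable_corpus():
    """15-video corpus with disjoint phase vocabularies and no
    pseudo-phase: the keyword-lookup-separable ground truth."""
    cfg = SyntheticConfig(
        n_videos=15,
        segments_per_phase=5.0,
        extra_insertion_prob=0.0,
        phase_skip_prob=0.0,
        synonym_rate=0.1,
        seed=11,
    )
    return generate_corpus(cfg), cfg


@pytest.fixture(scope="session")
def fixture_corpus():
    """Synthetic corpus whose (video, phase) counts equal the packaged
    study counts table exactly."""
    fix = table2_fixture()
    return corpus_from_counts(fix, SyntheticConfig(seed=5)), fix


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
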