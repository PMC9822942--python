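import numpy as np
import pytest

import phytomir as pm
from phytomir.synthetic import CorpusSpec


@pytest.fixture(scope="session")
def small_corpus():
    """A quick plant-regime corpus for unit tests."""
    return pm.generate_corpus(n_mirna=20, n_transcript=50, seed=11)


@pytest.fixture(scope="session")
def small_examples(small_corpus):
    return pm.corpus_to_examples(small_corpus)


@pytest.fixture(scope="session")
def study_corpus():
    """The package's default study corpus: 2,000 planted positives, seed 42."""
    return pm.generate_corpus(CorpusSpec())


@pytest.fixture(scope="session")
def study_examples(study_corpus):
    return pm.corpus_to_examples(study_corpus)


@pytest.fixture(scope="session")
def study_model(study_examples):
    """Forest trained on the first 80% of the study corpus (per class)."""
    train_ex, _ = split_holdout(study_examples, 0.8)
    return pm.train(train_ex, seed=42)


def split_holdout(examples, train_frac):
    """Deterministic per-class split: first train_frac of each class trains."""
    pos = [e for e in examples if e.y == 1]
    neg = [e for e in examples if e.y == 0]
    n_pos = int(len(pos) * train_frac)
    n_neg = int(len(neg) * train_frac)
    train = pos[:n_pos] + neg[:n_neg]
    test = pos[n_pos:] + neg[n_neg:]
    return train, test
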