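import numpy as np
import pandas as pd
import pytest

from cnvtriage.annotation import FINAL_FEATURES
from cnvtriage.synth import SynthGenomeSpec, generate_genome, synthetic_feature_matrix


@pytest.fixture(scope="session")
def genome():
    """One default synthetic genome shared across the suite."""
    return generate_genome(SynthGenomeSpec(), seed=1234)


@pytest.fixture(scope="session")
def small_dataset(genome):
    """Annotated 164 mr + 282 benign CNV set: enough for an 82+82
    training split with an 82+200 held-out test set."""
    X, y, _ = synthetic_feature_matrix(164, 282, seed=11, genome=genome)
    return X, y


@pytest.fixture(scope="session")
def small_dataset_final(small_dataset):
    X, y = small_dataset
    return X[list(FINAL_FEATURES)], y


def balanced_split(y, n_each, seed=0):
    """Deterministic balanced train/test index split."""
    rng = np.random.default_rng(seed)
    mr = rng.permutation(np.flatnonzero(y == "mr"))
    be = rng.permutation(np.flatnonzero(y == "benign"))
    train = np.concatenate([mr[:n_each], be[:n_each]])
    test = np.setdiff1d(np.arange(len(y)), train)
    return train, test


@pytest.fixture(scope="session")
def trained_model(small_dataset_final):
    from cnvtriage.nbtree import NbTreeParams, train_nbtree

    X, y = small_dataset_final
    train, test = balanced_split(y, 82, seed=5)
    model = train_nbtree(X.iloc[train], y[train], NbTreeParams(seed=5))
    return model, train, test
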