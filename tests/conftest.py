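import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from qsarfuse import ACTIVE, INACTIVE, NO_PREDICTION, UNKNOWN, PredictionTable

A, I, N = ACTIVE, INACTIVE, NO_PREDICTION


def make_table(votes, labels, ad=None, smiles=None):
    """Build a small PredictionTable from nested lists of vote codes."""
    votes = np.asarray(votes, dtype=np.int8)
    n, m = votes.shape
    if ad is None:
        ad = np.ones((n, m), dtype=bool)
    return PredictionTable(
        chemical_ids=[f"c{i}" for i in range(n)],
        model_names=[f"m{j}" for j in range(m)],
        votes=votes,
        ad_mask=np.asarray(ad, dtype=bool),
        true_labels=np.asarray(labels, dtype=np.int8),
        smiles=smiles,
    )


@pytest.fixture
def small_table():
    """4 chemicals x 3 models, mixed votes, one out-of-AD entry, one unknown label."""
    votes = [[A, A, I],
             [A, I, I],
             [I, I, I],
             [A, A, A]]
    ad = [[True, True, True],
          [True, False, True],
          [True, True, True],
          [True, True, True]]
    labels = [A, A, I, UNKNOWN]
    return make_table(votes, labels, ad)
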