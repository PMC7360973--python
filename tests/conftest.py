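import numpy as np
import pandas as pd
import pytest

from trimerfit.sitescan import AMINO_ACIDS, OFFSETS, ScoringMatrix


@pytest.fixture
def zero_matrix():
    return ScoringMatrix.constant(0.0, name="zero")


@pytest.fixture
def const_neg_matrix():
    return ScoringMatrix.constant(-1.0, name="minus-one")


def random_matrix(rng, low=-3.0, high=3.0):
    vals = rng.uniform(low, high, size=(len(AMINO_ACIDS), len(OFFSETS)))
    df = pd.DataFrame(vals, index=list(AMINO_ACIDS), columns=list(OFFSETS))
    return ScoringMatrix(df, name="random")


def random_sequence(rng, length):
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))
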