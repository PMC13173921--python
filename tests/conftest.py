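import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from wbtdc import ExpressionMatrix, PhenotypeTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """5 genes × 6 samples, log2-like values."""
    rng = np.random.default_rng(7)
    genes = ["gA", "gB", "gC", "gD", "gE"]
    samples = [f"s{i}" for i in range(6)]
    return ExpressionMatrix(
        genes, samples, rng.normal(8, 1, size=(5, 6)), "transformed"
    )


@pytest.fixture
def small_pheno():
    samples = [f"s{i}" for i in range(6)]
    return PhenotypeTable(samples, ["disease"] * 3 + ["control"] * 3)
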