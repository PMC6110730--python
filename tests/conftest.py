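import numpy as np
import pandas as pd
import pytest

from physprr import CorporaDataset


@pytest.fixture
def make_dataset():
    """Factory for small hand-written corpora datasets."""

    def _make(ages, corpora, species="test", pregnant=None):
        frame = pd.DataFrame(
            {
                "id": np.arange(1, len(ages) + 1),
                "age": np.asarray(ages, dtype=float),
                "corpora": np.asarray(corpora, dtype=int),
            }
        )
        if pregnant is not None:
            frame["pregnant"] = np.asarray(pregnant, dtype=int)
        return CorporaDataset(species, frame)

    return _make


@pytest.fixture
def random_life_table():
    """Factory for random small survivorship tables (l(B) = 1, non-increasing)."""

    def _make(rng, max_ages=8):
        n = int(rng.integers(3, max_ages + 1))
        start = int(rng.integers(0, 6))
        drops = rng.uniform(0.0, 1.0, size=n - 1)
        lx = np.concatenate([[1.0], np.cumprod(1.0 - 0.6 * drops)])
        ages = np.arange(start, start + n, dtype=float)
        from physprr import LifeTable

        return LifeTable(ages, lx, 0.0)

    return _make
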