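from __future__ import annotations

import numpy as np
import pytest

from pacobn.dataset import DiscreteDataset, SignalDataset


def make_discrete(levels, cards=None, labels=None) -> DiscreteDataset:
    """Build a DiscreteDataset from a plain nested list of levels."""
    levels = np.asarray(levels, dtype=np.int64)
    if cards is None:
        cards = (levels.max(axis=0) + 1).tolist()
    if labels is None:
        labels = [f"X{i + 1}" for i in range(levels.shape[1])]
    return DiscreteDataset(levels, cards, labels)


def random_discrete(rng: np.random.Generator, v: int, m: int,
                    max_card: int = 3) -> DiscreteDataset:
    """Random categorical data with per-column cardinalities in [2, max_card]."""
    cards = rng.integers(2, max_card + 1, size=v)
    levels = np.column_stack([rng.integers(0, r, size=m) for r in cards])
    # realize as many declared levels as the sample count allows
    for i, r in enumerate(cards):
        k = min(int(r), m)
        levels[:k, i] = np.arange(k)
    return DiscreteDataset(levels, cards.tolist(),
                           [f"X{i + 1}" for i in range(v)])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def chain3_dataset(rng) -> DiscreteDataset:
    """200 samples of a noisy binary chain X1 -> X2 -> X3 (discrete)."""
    m = 200
    x1 = rng.integers(0, 2, m)
    flip2 = rng.random(m) < 0.15
    x2 = np.where(flip2, 1 - x1, x1)
    flip3 = rng.random(m) < 0.15
    x3 = np.where(flip3, 1 - x2, x2)
    return make_discrete(np.column_stack([x1, x2, x3]))


@pytest.fixture
def independent_dataset(rng) -> DiscreteDataset:
    """Three mutually independent binary columns, 300 samples."""
    return make_discrete(rng.integers(0, 2, size=(300, 3)))


@pytest.fixture
def signal_3x2() -> SignalDataset:
    return SignalDataset(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]),
                         ["A", "B"])
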