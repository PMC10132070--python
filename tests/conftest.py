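"""Shared fixtures and helpers for the suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")

_POINT = {"A": "C", "C": "G", "G": "T", "T": "A"}


def mutate(seq: str, n_or_frac: float, rng: np.random.Generator,
           positions: list[int] | None = None) -> str:
    """Apply point substitutions (never identity) at random positions."""
    chars = list(seq)
    if positions is None:
        k = n_or_frac if isinstance(n_or_frac, int) else int(n_or_frac * len(seq))
        positions = rng.choice(len(seq), size=k, replace=False)
    for p in positions:
        chars[p] = _POINT[chars[p]]
    return "".join(chars)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
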