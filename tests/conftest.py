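from __future__ import annotations

import numpy as np
import pytest

from sumohydro.alphabet import AMINO_ACIDS, PAD
from sumohydro.dataset import Fragment, LabeledDataset, NEGATIVE, POSITIVE


def make_fragment(core: str, label: int = NEGATIVE, source=None, window: int = 25) -> Fragment:
    """Pad a short K-centred core out to a full window with O runs."""
    assert len(core) % 2 == 1 and core[len(core) // 2] == "K"
    flank = (window - len(core)) // 2
    return Fragment(
        residues=PAD * flank + core + PAD * flank,
        label=label,
        source=source or (f"core:{core}", 1),
    )


def random_fragment(rng: np.random.Generator, label: int = NEGATIVE, source=None,
                    window: int = 25) -> Fragment:
    """A random full-window fragment with random terminal padding."""
    half = window // 2
    left_pad = int(rng.integers(0, half))
    right_pad = int(rng.integers(0, half))
    left = "".join(rng.choice(list(AMINO_ACIDS), size=half - left_pad))
    right = "".join(rng.choice(list(AMINO_ACIDS), size=half - right_pad))
    residues = PAD * left_pad + left + "K" + right + PAD * right_pad
    if source is None:
        source = (f"rand{rng.integers(1 << 30)}", half + 1)
    return Fragment(residues=residues, label=label, source=source)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20120614)


@pytest.fixture
def toy_dataset(rng) -> LabeledDataset:
    frags = [
        random_fragment(rng, label=POSITIVE, source=(f"P{i}", 13)) for i in range(5)
    ] + [
        random_fragment(rng, label=NEGATIVE, source=(f"N{i}", 13)) for i in range(20)
    ]
    return LabeledDataset(fragments=frags)
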