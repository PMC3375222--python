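"""Fragment alphabet shared by the dataset and encoder layers.

Fragments are written over 21 letters: the 20 standard amino acids in
alphabetical one-letter order, plus ``O``, an artificial padding symbol
used to fill window positions that fall outside a protein's termini.
"""

from __future__ import annotations

import numpy as np

#: 21-letter fragment alphabet, alphabetical, padding symbol last.
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWYO"

#: The 20 standard amino-acid one-letter codes (no padding symbol).
AMINO_ACIDS: str = ALPHABET[:20]

#: Padding symbol for out-of-protein window positions.
PAD: str = "O"

#: letter -> index over the full 21-letter alphabet (A=0 ... O=20).
LETTER_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET)}

#: Index of the padding symbol.
PAD_INDEX: int = LETTER_INDEX[PAD]


def encode_letters(residues: str) -> np.ndarray:
    """Map a residue string to integer codes over the 21-letter alphabet.

    Raises
    ------
    ValueError
        If any character is outside the alphabet.
    """
    try:
        return np.array([LETTER_INDEX[c] for c in residues], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(
            f"character {exc.args[0]!r} is not in the fragment alphabet {ALPHABET}"
        ) from None
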