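"""Feature encodings for lysine-centred sequence fragments.

Eight schemes are provided, each a pure function Fragment -> vector:

========== =========================================== =========
scheme     description                                 dimension
========== =========================================== =========
binary     one-hot per non-centre position             21*2n (504)
cksaap     k-spaced ordered pair counts, k=0..k_max    441*(k_max+1)
six_letter one-hot over a 6-group reduced alphabet     6*2n (144)
nine_letter one-hot over a 9-group reduced alphabet    9*2n (216)
zscales    five physicochemical descriptors/position   5*2n (120)
hydrobinary binary + hydrophobicity at offsets -1..+2  21*2n+4 (508)
pssm       PSI-BLAST log-odds row per window position  20*(2n+1) (500)
knn        ratio of mean distances to k nearest        len(k_list)
           positive vs negative reference fragments
========== =========================================== =========

The padding symbol O is neutral under every scheme: hydrophobicity 0,
zero Z-scales, zero PSSM row, and BLOSUM similarity 1 to itself / 0 to
every amino acid.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .alphabet import ALPHABET, AMINO_ACIDS, LETTER_INDEX, PAD, PAD_INDEX
from .dataset import Fragment, LabeledDataset

N_LETTERS = len(ALPHABET)  # 21

DEFAULT_KNN_K = (1, 3, 5, 7, 9, 15)

SCHEMES = (
    "binary",
    "cksaap",
    "pssm",
    "knn",
    "six_letter",
    "nine_letter",
    "hydrobinary",
    "zscales",
)


class EncodingError(ValueError):
    """Raised on invalid encoder inputs or missing scheme resources."""


# ---------------------------------------------------------------------------
# Physicochemical tables
# ---------------------------------------------------------------------------

#: Per-residue hydrophobicity scale (padding symbol O is neutral at 0).
HYDROPHOBICITY: dict[str, float] = {
    "A": 1.81, "C": 1.28, "D": -8.72, "E": -6.81, "F": 2.98,
    "G": 0.94, "H": -4.66, "I": 4.92, "K": -5.55, "L": 4.92,
    "M": 2.35, "N": -6.64, "P": 4.04, "Q": -5.54, "R": -14.92,
    "S": -3.40, "T": -2.57, "V": 4.04, "W": 2.33, "Y": -0.14,
    PAD: 0.0,
}

#: Five-descriptor Z-scales per residue (padding symbol O is all-zero).
ZSCALES: dict[str, tuple[float, float, float, float, float]] = {
    "A": (0.24, -2.32, 0.60, -0.14, 1.30),
    "C": (0.84, -1.67, 3.71, 0.18, -2.65),
    "D": (3.98, 0.93, 1.93, -2.46, 0.75),
    "E": (3.11, 0.26, -0.11, -3.04, -0.25),
    "F": (-4.22, 1.94, 1.06, 0.54, -0.62),
    "G": (2.05, -4.06, 0.36, -0.82, -0.38),
    "H": (2.47, 1.95, 0.26, 3.90, 0.09),
    "I": (-3.89, -1.73, -1.71, -0.84, 0.26),
    "K": (2.29, 0.89, -2.49, 1.49, 0.31),
    "L": (-4.28, -1.30, -1.49, -0.72, 0.84),
    "M": (-2.85, -0.22, 0.47, 1.94, -0.98),
    "N": (3.05, 1.62, 1.04, -1.15, 1.61),
    "P": (-1.66, 0.27, 1.84, 0.70, 2.00),
    "Q": (1.75, 0.50, -1.44, -1.34, 0.66),
    "R": (3.52, 2.50, -3.50, 1.99, -0.17),
    "S": (2.39, -1.07, 1.15, -1.39, 0.67),
    "T": (0.75, -2.18, -1.12, -1.46, -0.40),
    "V": (-2.59, -2.64, -1.54, -0.85, -0.02),
    "W": (-4.36, 3.94, 0.59, 3.44, -1.59),
    "Y": (-2.54, 2.44, 0.43, 0.04, -1.47),
    PAD: (0.0, 0.0, 0.0, 0.0, 0.0),
}

# Reduced alphabets.  Group order is the encoding order.
SIX_GROUPS: tuple[tuple[str, str], ...] = (
    ("aliphatic", "AVLI"),
    ("charged", "DERK"),
    ("polar", "STNQ"),
    ("cyclic", "FHYW"),
    ("other", "GPMC"),
    ("pad", PAD),
)
NINE_GROUPS: tuple[tuple[str, str], ...] = (
    ("aliphatic", "AVLI"),
    ("charged", "DERK"),
    ("polar", "STNQ"),
    ("cyclic", "FHYW"),
    ("glycine", "G"),
    ("proline", "P"),
    ("methionine", "M"),
    ("cysteine", "C"),
    ("pad", PAD),
)


def _group_index(groups: tuple[tuple[str, str], ...]) -> dict[str, int]:
    return {letter: gi for gi, (_, letters) in enumerate(groups) for letter in letters}


REDUCED_MAPS: dict[str, dict[str, int]] = {
    "six": _group_index(SIX_GROUPS),
    "nine": _group_index(NINE_GROUPS),
}
REDUCED_SIZES = {"six": len(SIX_GROUPS), "nine": len(NINE_GROUPS)}


def hydrophobicity(letter: str) -> float:
    """Hydrophobicity value for a single alphabet letter (O -> 0.0)."""
    try:
        return HYDROPHOBICITY[letter]
    except KeyError:
        raise EncodingError(f"unknown letter {letter!r}") from None


# ---------------------------------------------------------------------------
# BLOSUM62-derived similarity
# ---------------------------------------------------------------------------


@lru_cache(maxsize=1)
def normalized_blosum() -> np.ndarray:
    """21x21 similarity matrix in [0, 1] over the fragment alphabet.

    The 20x20 BLOSUM62 block is min-max rescaled to [0, 1]; the padding
    symbol gets similarity 1 to itself and 0 to every amino acid.
    """
    blosum = substitution_matrices.load("BLOSUM62")
    sim = np.zeros((N_LETTERS, N_LETTERS))
    block = np.array(
        [[blosum[a, b] for b in AMINO_ACIDS] for a in AMINO_ACIDS], dtype=float
    )
    lo, hi = block.min(), block.max()
    sim[:20, :20] = (block - lo) / (hi - lo)
    sim[PAD_INDEX, PAD_INDEX] = 1.0
    return sim


def knn_distance(a: Fragment, b: Fragment, sim: np.ndarray | None = None) -> float:
    """Mean over positions of (1 - similarity) between two fragments.

    Bounded in [0, 1] and symmetric; 0 iff every aligned pair attains
    maximal similarity.
    """
    if len(a.residues) != len(b.residues):
        raise EncodingError(
            f"fragment length mismatch: {len(a.residues)} vs {len(b.residues)}"
        )
    if sim is None:
        sim = normalized_blosum()
    return float(np.mean(1.0 - sim[a.codes(), b.codes()]))


# ---------------------------------------------------------------------------
# Per-fragment encoders
# ---------------------------------------------------------------------------


def _noncenter_codes(f: Fragment) -> np.ndarray:
    codes = f.codes()
    c = f.center
    return np.concatenate([codes[:c], codes[c + 1 :]])


def encode_binary(f: Fragment) -> np.ndarray:
    """One-hot over the 21-letter alphabet for each non-centre position.

    The constant central K carries no information and is skipped, giving
    dimension 21*2n (504 for the default 25-mer).
    """
    codes = _noncenter_codes(f)
    vec = np.zeros(codes.size * N_LETTERS)
    vec[np.arange(codes.size) * N_LETTERS + codes] = 1.0
    return vec


def encode_cksaap(f: Fragment, k_max: int = 4) -> np.ndarray:
    """Counts of ordered letter pairs separated by k letters, k=0..k_max.

    The whole fragment (centre K included) is scanned; each spacing
    contributes a 441-entry block ordered row-major by alphabet index,
    for a total of 441*(k_max+1) raw integer counts.
    """
    if k_max < 0:
        raise EncodingError(f"k_max must be >= 0, got {k_max}")
    codes = f.codes()
    m = codes.size
    vec = np.zeros(N_LETTERS * N_LETTERS * (k_max + 1))
    for k in range(k_max + 1):
        left = codes[: m - k - 1]
        right = codes[k + 1 :]
        block = np.bincount(
            left.astype(np.int64) * N_LETTERS + right, minlength=N_LETTERS * N_LETTERS
        )
        vec[k * 441 : (k + 1) * 441] = block
    return vec


def encode_reduced(f: Fragment, variant: str) -> np.ndarray:
    """One-hot over a reduced group alphabet for each non-centre position."""
    if variant not in REDUCED_MAPS:
        raise EncodingError(f"unknown variant {variant!r}; expected 'six' or 'nine'")
    gmap = REDUCED_MAPS[variant]
    size = REDUCED_SIZES[variant]
    c = f.center
    letters = f.residues[:c] + f.residues[c + 1 :]
    vec = np.zeros(len(letters) * size)
    for i, letter in enumerate(letters):
        vec[i * size + gmap[letter]] = 1.0
    return vec


def encode_zscales(f: Fragment) -> np.ndarray:
    """Concatenated (z1..z5) descriptors for the non-centre positions."""
    c = f.center
    letters = f.residues[:c] + f.residues[c + 1 :]
    return np.array([v for letter in letters for v in ZSCALES[letter]])


def encode_hydrobinary(f: Fragment) -> np.ndarray:
    """Binary encoding plus hydrophobicity at offsets -1, 0, +1, +2.

    The four hydrophobicity slots cover one residue upstream of the
    central K through two residues downstream (the motif's hydrophobic
    region), appended after the 504 one-hot components: total 508.
    """
    c = f.center
    tail = [hydrophobicity(f.residues[c + off]) for off in (-1, 0, 1, 2)]
    return np.concatenate([encode_binary(f), np.array(tail)])


# ---------------------------------------------------------------------------
# PSSM profiles
# ---------------------------------------------------------------------------

#: NCBI PSSM column order (differs from our alphabetical order).
_NCBI_ORDER = "ARNDCQEGHILKMFPSTWYV"
_NCBI_TO_ALPHA = [_NCBI_ORDER.index(a) for a in AMINO_ACIDS]


@dataclass(frozen=True)
class PssmProfile:
    """Per-position log-odds scores for one protein.

    ``scores`` has one row per residue, columns in alphabetical
    amino-acid order (ACDEFGHIKLMNPQRSTVWY).
    """

    protein_id: str
    residues: str
    scores: np.ndarray  # shape (len(residues), 20)

    def __post_init__(self) -> None:
        if self.scores.shape != (len(self.residues), 20):
            raise EncodingError(
                f"profile {self.protein_id!r}: scores shape {self.scores.shape} "
                f"does not match {len(self.residues)} residues"
            )


def parse_pssm(path: str | Path, protein_id: str | None = None) -> PssmProfile:
    """Parse an NCBI PSI-BLAST ASCII PSSM (the 20-column log-odds block)."""
    path = Path(path)
    residues: list[str] = []
    rows: list[list[int]] = []
    row_re = re.compile(r"^\s*(\d+)\s+([A-Z])((?:\s+-?\d+){20,})")
    with open(path) as handle:
        for line in handle:
            m = row_re.match(line)
            if not m:
                continue
            residues.append(m.group(2))
            values = [int(v) for v in m.group(3).split()[:20]]
            rows.append(values)
    if not rows:
        raise EncodingError(f"{path}: no PSSM rows found")
    ncbi = np.array(rows, dtype=float)
    return PssmProfile(
        protein_id=protein_id or path.stem,
        residues="".join(residues),
        scores=ncbi[:, _NCBI_TO_ALPHA],
    )


def encode_pssm(f: Fragment, profile: PssmProfile) -> np.ndarray:
    """Concatenated PSSM rows over all window positions (padded -> zeros)."""
    pid, pos = f.source
    length = len(profile.residues)
    c = f.center
    out = np.zeros((len(f.residues), 20))
    for i, letter in enumerate(f.residues):
        p = pos - c + i  # 1-based protein coordinate of window slot i
        if letter == PAD:
            continue
        if not 1 <= p <= length:
            raise EncodingError(
                f"profile {profile.protein_id!r} does not cover position {p} "
                f"needed by fragment {f.source}"
            )
        if profile.residues[p - 1] != letter:
            raise EncodingError(
                f"profile {profile.protein_id!r} residue mismatch at {p}: "
                f"profile has {profile.residues[p - 1]!r}, fragment has {letter!r}"
            )
        out[i] = profile.scores[p - 1]
    return out.ravel()


# ---------------------------------------------------------------------------
# KNN encoding
# ---------------------------------------------------------------------------


def _distance_matrix(queries: np.ndarray, refs: np.ndarray, sim: np.ndarray) -> np.ndarray:
    """Pairwise mean (1 - similarity) between code matrices."""
    # (q, 1, m) x (1, r, m) gather — vectorised over positions
    return 1.0 - sim[queries[:, None, :], refs[None, :, :]].mean(axis=2)


def encode_knn(
    f: Fragment,
    positives: Sequence[Fragment],
    negatives: Sequence[Fragment],
    k_list: Sequence[int] = DEFAULT_KNN_K,
    sim: np.ndarray | None = None,
    exclude_self: bool = True,
) -> np.ndarray:
    """Ratios D_p/D_n of mean distances to the k nearest positive and
    negative reference fragments, one feature per k.

    If ``exclude_self`` is set (default), any reference fragment with the
    same source as ``f`` is dropped before neighbour search, so a
    training fragment never matches itself.
    """
    if sim is None:
        sim = normalized_blosum()
    if exclude_self:
        positives = [r for r in positives if r.source != f.source]
        negatives = [r for r in negatives if r.source != f.source]
    kmax = max(k_list)
    if len(positives) < kmax or len(negatives) < kmax:
        raise EncodingError(
            f"reference sets too small for k={kmax}: "
            f"{len(positives)} positives, {len(negatives)} negatives"
        )
    q = f.codes()[None, :]
    dp_all = np.sort(_distance_matrix(q, np.stack([r.codes() for r in positives]), sim)[0])
    dn_all = np.sort(_distance_matrix(q, np.stack([r.codes() for r in negatives]), sim)[0])
    feats = []
    for k in k_list:
        d_p = float(dp_all[:k].mean())
        d_n = float(dn_all[:k].mean())
        if d_n == 0.0:
            raise EncodingError(
                f"degenerate negative reference: D_n = 0 at k={k} for {f.source}"
            )
        feats.append(d_p / d_n)
    return np.array(feats)


# ---------------------------------------------------------------------------
# Dataset-level encoding
# ---------------------------------------------------------------------------


def scheme_dimension(
    scheme: str,
    window: int = 25,
    k_max: int = 4,
    k_list: Sequence[int] = DEFAULT_KNN_K,
) -> int:
    """Feature dimension contract for a scheme at a given window size."""
    flank2 = window - 1
    dims = {
        "binary": N_LETTERS * flank2,
        "cksaap": 441 * (k_max + 1),
        "six_letter": 6 * flank2,
        "nine_letter": 9 * flank2,
        "zscales": 5 * flank2,
        "hydrobinary": N_LETTERS * flank2 + 4,
        "pssm": 20 * window,
        "knn": len(k_list),
    }
    if scheme not in dims:
        raise EncodingError(f"unknown scheme {scheme!r}; valid: {', '.join(SCHEMES)}")
    return dims[scheme]


def encode_fragment(
    f: Fragment,
    scheme: str,
    *,
    k_max: int = 4,
    profiles: dict[str, PssmProfile] | None = None,
    ref_positives: Sequence[Fragment] | None = None,
    ref_negatives: Sequence[Fragment] | None = None,
    k_list: Sequence[int] = DEFAULT_KNN_K,
    exclude_self: bool = True,
) -> np.ndarray:
    """Encode one fragment under any scheme (dispatch helper)."""
    if scheme == "binary":
        return encode_binary(f)
    if scheme == "cksaap":
        return encode_cksaap(f, k_max=k_max)
    if scheme == "six_letter":
        return encode_reduced(f, "six")
    if scheme == "nine_letter":
        return encode_reduced(f, "nine")
    if scheme == "zscales":
        return encode_zscales(f)
    if scheme == "hydrobinary":
        return encode_hydrobinary(f)
    if scheme == "pssm":
        if profiles is None or f.source[0] not in profiles:
            raise EncodingError(f"pssm encoding requires a profile for {f.source[0]!r}")
        return encode_pssm(f, profiles[f.source[0]])
    if scheme == "knn":
        if ref_positives is None or ref_negatives is None:
            raise EncodingError("knn encoding requires reference fragment sets")
        return encode_knn(
            f, ref_positives, ref_negatives, k_list=k_list, exclude_self=exclude_self
        )
    raise EncodingError(f"unknown scheme {scheme!r}; valid: {', '.join(SCHEMES)}")


def encode_dataset(
    dataset: LabeledDataset | Iterable[Fragment],
    scheme: str,
    **options,
) -> tuple[np.ndarray, np.ndarray]:
    """Encode a dataset into a feature matrix and label vector.

    Row order matches dataset order.  For the KNN scheme the reference
    sets default to the dataset itself, with each fragment excluded from
    its own reference set (leave-self-out).
    """
    fragments = list(dataset)
    if scheme == "knn":
        options.setdefault("ref_positives", [f for f in fragments if f.label == 1])
        options.setdefault("ref_negatives", [f for f in fragments if f.label == 0])
    X = np.stack([encode_fragment(f, scheme, **options) for f in fragments])
    y = np.array([f.label for f in fragments], dtype=np.int64)
    return X, y
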