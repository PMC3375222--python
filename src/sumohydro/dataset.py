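"""Labeled fragment datasets: FASTA/site-table input, lysine-window
extraction with terminal padding, redundancy filtering and seeded
negative subsampling.

Coordinates: site positions are 1-based on the protein sequence
everywhere in file formats and public signatures; indices into fragment
strings are 0-based internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .alphabet import ALPHABET, AMINO_ACIDS, PAD, encode_letters

POSITIVE = 1
NEGATIVE = 0

DEFAULT_FLANK = 12  # residues on each side of the central K; window = 2*12+1 = 25


class DatasetError(ValueError):
    """Raised on malformed input files or violated dataset preconditions."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence over the 20 standard amino-acid letters."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DatasetError(f"protein {self.id!r}: empty sequence")
        for i, c in enumerate(self.sequence):
            if c not in AMINO_ACIDS:
                raise DatasetError(
                    f"protein {self.id!r}: non-standard residue {c!r} at position {i + 1}"
                )


@dataclass(frozen=True)
class SiteAnnotation:
    """A labeled lysine site: 1-based position on a named protein."""

    protein_id: str
    position: int
    label: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise DatasetError(
                f"site {self.protein_id}:{self.position}: position must be >= 1"
            )
        if self.label not in (POSITIVE, NEGATIVE):
            raise DatasetError(
                f"site {self.protein_id}:{self.position}: label must be 0 or 1"
            )


@dataclass(frozen=True)
class Fragment:
    """A fixed-length window centred on a lysine, padded with O at the termini."""

    residues: str
    label: int
    source: tuple[str, int]  # (protein_id, 1-based position of the central K)

    def __post_init__(self) -> None:
        m = len(self.residues)
        if m % 2 == 0:
            raise DatasetError(f"fragment {self.source}: even length {m}")
        center = m // 2
        if self.residues[center] != "K":
            raise DatasetError(
                f"fragment {self.source}: central residue is "
                f"{self.residues[center]!r}, expected 'K'"
            )
        for c in self.residues:
            if c not in ALPHABET:
                raise DatasetError(
                    f"fragment {self.source}: character {c!r} outside alphabet"
                )
        core = self.residues.strip(PAD)
        if PAD in core:
            raise DatasetError(
                f"fragment {self.source}: padding symbol O inside the window core"
            )

    @property
    def center(self) -> int:
        return len(self.residues) // 2

    def codes(self) -> np.ndarray:
        return encode_letters(self.residues)


@dataclass
class LabeledDataset:
    """An ordered collection of fragments plus provenance metadata."""

    fragments: list[Fragment]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for f in self.fragments:
            if f.source in seen:
                raise DatasetError(f"duplicate fragment source {f.source}")
            seen.add(f.source)

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    @property
    def positives(self) -> list[Fragment]:
        return [f for f in self.fragments if f.label == POSITIVE]

    @property
    def negatives(self) -> list[Fragment]:
        return [f for f in self.fragments if f.label == NEGATIVE]

    def labels(self) -> np.ndarray:
        return np.array([f.label for f in self.fragments], dtype=np.int64)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into :class:`ProteinRecord` objects.

    The header token before the first whitespace becomes the id and
    sequences are uppercased.  Non-standard residue letters (B, J, O, U,
    X, Z, ``*`` ...) are rejected with the protein id and 1-based
    position in the message.
    """
    path = Path(path)
    with open(path) as handle:
        first = handle.readline()
        if not first.startswith(">"):
            raise DatasetError(
                f"{path}: not FASTA — line 1 does not start with '>': {first.rstrip()!r}"
            )
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq).upper()))
    if not records:
        raise DatasetError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")


def read_site_table(path: str | Path) -> list[SiteAnnotation]:
    """Read a TSV of (protein_id, 1-based position, label in {1,0})."""
    path = Path(path)
    sites = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise DatasetError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
                )
            pid, pos_s, label_s = parts
            if pid == "protein_id":  # header row
                continue
            try:
                pos, label = int(pos_s), int(label_s)
            except ValueError:
                raise DatasetError(
                    f"{path}:{lineno}: position and label must be integers"
                ) from None
            sites.append(SiteAnnotation(pid, pos, label))
    return sites


def write_site_table(sites: Iterable[SiteAnnotation], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("protein_id\tposition\tlabel\n")
        for s in sites:
            out.write(f"{s.protein_id}\t{s.position}\t{s.label}\n")


def read_fragment_list(path: str | Path, label: int) -> list[Fragment]:
    """Read a plain fragment list (one fixed-length window per line).

    This is the dialect of the deposited Positive_K / Negative_K style
    files.  Sources are synthesised as ``(<file stem>:<line>, <flank+1>)``
    since the originating proteins are not recorded in that format.
    """
    path = Path(path)
    fragments = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            s = line.strip().upper()
            if not s:
                continue
            fragments.append(
                Fragment(
                    residues=s,
                    label=label,
                    source=(f"{path.stem}:{lineno}", len(s) // 2 + 1),
                )
            )
    if not fragments:
        raise DatasetError(f"{path}: no fragments found")
    return fragments


def write_fragment_list(fragments: Iterable[Fragment], path: str | Path) -> None:
    with open(path, "w") as out:
        for f in fragments:
            out.write(f.residues + "\n")


# ---------------------------------------------------------------------------
# Fragment construction
# ---------------------------------------------------------------------------


def extract_fragment(
    protein: ProteinRecord, position: int, n: int = DEFAULT_FLANK, label: int = NEGATIVE
) -> Fragment:
    """Extract the 2n+1 window centred on a K at 1-based ``position``.

    Window positions before residue 1 or after the last residue are
    filled with the padding symbol O.
    """
    seq = protein.sequence
    if not 1 <= position <= len(seq):
        raise DatasetError(
            f"protein {protein.id!r}: position {position} out of range 1..{len(seq)}"
        )
    if seq[position - 1] != "K":
        raise DatasetError(
            f"protein {protein.id!r}: residue at position {position} is "
            f"{seq[position - 1]!r}, expected 'K'"
        )
    i = position - 1
    left = seq[max(0, i - n) : i]
    right = seq[i + 1 : i + 1 + n]
    residues = PAD * (n - len(left)) + left + "K" + right + PAD * (n - len(right))
    return Fragment(residues=residues, label=label, source=(protein.id, position))


def build_candidate_set(
    proteins: Sequence[ProteinRecord],
    positive_annotations: Sequence[SiteAnnotation],
    n: int = DEFAULT_FLANK,
) -> LabeledDataset:
    """Build the full candidate dataset: one positive fragment per
    annotation, one negative per remaining K across all proteins.

    Positives come first (protein order, then position), then negatives,
    so that a subsequent greedy redundancy filter preferentially retains
    positives.  Duplicate annotations are collapsed with a warning;
    annotations pointing at a non-K residue raise an error listing all
    offenders.
    """
    by_id = {p.id: p for p in proteins}
    positive_keys: set[tuple[str, int]] = set()
    offenders = []
    for ann in positive_annotations:
        key = (ann.protein_id, ann.position)
        if key in positive_keys:
            warnings.warn(f"duplicate annotation {key} collapsed", stacklevel=2)
            continue
        prot = by_id.get(ann.protein_id)
        if prot is None:
            offenders.append(f"{ann.protein_id}:{ann.position} (unknown protein)")
            continue
        if not (1 <= ann.position <= len(prot.sequence)) or prot.sequence[
            ann.position - 1
        ] != "K":
            offenders.append(f"{ann.protein_id}:{ann.position} (not a K)")
            continue
        positive_keys.add(key)
    if offenders:
        raise DatasetError(
            "positive annotations do not resolve to a K: " + ", ".join(offenders)
        )

    positives, negatives = [], []
    for prot in proteins:
        for i, c in enumerate(prot.sequence):
            if c != "K":
                continue
            pos = i + 1
            if (prot.id, pos) in positive_keys:
                positives.append(extract_fragment(prot, pos, n, label=POSITIVE))
            else:
                negatives.append(extract_fragment(prot, pos, n, label=NEGATIVE))
    return LabeledDataset(
        fragments=positives + negatives,
        metadata={"window_flank": n, "n_positives": len(positives), "n_negatives": len(negatives)},
    )


# ---------------------------------------------------------------------------
# Redundancy filtering and subsampling
# ---------------------------------------------------------------------------


def fragment_identity(a: Fragment, b: Fragment) -> float:
    """Ungapped positional identity between two equal-length fragments.

    Fraction of positions with identical characters; padding matching
    padding counts as identical.  Symmetric by construction.
    """
    if len(a.residues) != len(b.residues):
        raise DatasetError(
            f"fragment length mismatch: {len(a.residues)} vs {len(b.residues)}"
        )
    same = sum(x == y for x, y in zip(a.residues, b.residues))
    return same / len(a.residues)


def redundancy_filter(dataset: LabeledDataset, threshold: float = 0.40) -> LabeledDataset:
    """Greedy single-pass redundancy removal in dataset order.

    A fragment is kept iff its identity with every previously kept
    fragment (positives and negatives pooled) is strictly below
    ``threshold``; hence all surviving pairs satisfy the bound.
    Deterministic and idempotent.
    """
    if not 0 < threshold <= 1:
        raise DatasetError(f"threshold must be in (0, 1], got {threshold}")
    if len(dataset) == 0:
        raise DatasetError("cannot filter an empty dataset")
    m = len(dataset.fragments[0].residues)
    codes = np.stack([f.codes() for f in dataset.fragments])
    kept_idx: list[int] = []
    kept_codes = np.empty((0, m), dtype=np.int8)
    for i, row in enumerate(codes):
        if kept_codes.shape[0]:
            ident = (kept_codes == row).mean(axis=1)
            if float(ident.max()) >= threshold:
                continue
        kept_idx.append(i)
        kept_codes = np.vstack([kept_codes, row[None, :]])
    meta = dict(dataset.metadata)
    meta["identity_threshold"] = threshold
    return LabeledDataset(
        fragments=[dataset.fragments[i] for i in kept_idx], metadata=meta
    )


def sample_negatives(
    dataset: LabeledDataset, ratio: int = 10, seed: int = 0
) -> LabeledDataset:
    """Keep all positives and a seeded uniform sample (without
    replacement) of ``ratio`` negatives per positive, in original order.
    """
    positives = dataset.positives
    negatives = dataset.negatives
    required = ratio * len(positives)
    if required > len(negatives):
        raise DatasetError(
            f"insufficient negatives: need {required}, have {len(negatives)}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(negatives), size=required, replace=False)
    chosen_set = set(int(i) for i in chosen)
    sampled = [f for i, f in enumerate(negatives) if i in chosen_set]
    meta = dict(dataset.metadata)
    meta.update({"sampling_ratio": ratio, "sampling_seed": seed})
    return LabeledDataset(fragments=positives + sampled, metadata=meta)
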