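"""Seeded synthetic proteomes with planted sumoylation signal.

Generates background protein sequences and plants positive lysines with
the hydrophobic-K-x-E consensus context (large hydrophobic residue one
position upstream, glutamate two downstream).  Every remaining K is a
negative.  Exists solely to make the rest of the package testable
without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataset import (
    NEGATIVE,
    POSITIVE,
    ProteinRecord,
    SiteAnnotation,
    write_fasta,
    write_fragment_list,
    write_site_table,
    build_candidate_set,
)
from .alphabet import AMINO_ACIDS

#: Large hydrophobic residues accepted at the -1 (psi) motif position.
PSI_RESIDUES = "VILMF"

# Approximate Swiss-Prot background residue frequencies.
SWISSPROT_FREQS: dict[str, float] = {
    "A": 0.0826, "C": 0.0139, "D": 0.0546, "E": 0.0672, "F": 0.0387,
    "G": 0.0708, "H": 0.0228, "I": 0.0593, "K": 0.0581, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0475, "Q": 0.0393, "R": 0.0553,
    "S": 0.0665, "T": 0.0535, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}


class SyntheticError(ValueError):
    """Raised when a synthetic configuration cannot be satisfied."""


@dataclass
class SyntheticConfig:
    """Parameters for a planted-motif proteome.

    ``n_proteins=None`` sizes the proteome automatically so the expected
    negative:positive ratio approaches ``imbalance_target``.  A fraction
    of positives (default 26%) is planted without the consensus context,
    mimicking non-consensus sumoylation events.
    """

    n_positives: int = 100
    n_proteins: int | None = None
    min_length: int = 60
    max_length: int = 400
    nonconsensus_fraction: float = 0.26
    imbalance_target: float = 25.0
    background: str = "uniform"  # or "swissprot"
    clean_negatives: bool = True  # strip accidental consensus context from negatives
    seed: int = 0

    def frequencies(self) -> tuple[np.ndarray, str]:
        if self.background == "uniform":
            return np.full(20, 1 / 20), AMINO_ACIDS
        if self.background == "swissprot":
            freqs = np.array([SWISSPROT_FREQS[a] for a in AMINO_ACIDS])
            return freqs / freqs.sum(), AMINO_ACIDS
        raise SyntheticError(
            f"unknown background {self.background!r}; valid: uniform, swissprot"
        )


@dataclass
class Proteome:
    """Generated proteins with their ground-truth site table."""

    proteins: list[ProteinRecord]
    positive_annotations: list[SiteAnnotation]
    all_sites: list[SiteAnnotation] = field(default_factory=list)
    config: SyntheticConfig | None = None


def _has_consensus(seq: str, i: int) -> bool:
    """Consensus context around a 0-based K index: psi at -1 and E at +2."""
    return (
        i - 1 >= 0
        and i + 2 < len(seq)
        and seq[i - 1] in PSI_RESIDUES
        and seq[i + 2] == "E"
    )


def generate_proteome(config: SyntheticConfig) -> Proteome:
    """Generate a seeded proteome with planted positive lysines.

    Positives are embedded as psi/K/x/E (psi drawn uniformly from
    VILMF); a configured fraction is instead planted without that
    context.  All other K residues are negatives; when
    ``clean_negatives`` is set, background lysines that happen to carry
    the consensus context get it mutated away so ground truth stays
    separable.
    """
    rng = np.random.default_rng(config.seed)
    freqs, letters = config.frequencies()
    k_freq = freqs[letters.index("K")]

    n_proteins = config.n_proteins
    if n_proteins is None:
        mean_len = (config.min_length + config.max_length) / 2
        total_needed = (config.imbalance_target + 1) * config.n_positives / k_freq
        n_proteins = max(1, int(np.ceil(total_needed / mean_len)))

    letter_arr = np.array(list(letters))
    seqs: list[list[str]] = []
    for _ in range(n_proteins):
        length = int(rng.integers(config.min_length, config.max_length + 1))
        seqs.append(list(rng.choice(letter_arr, size=length, p=freqs)))

    # choose planting slots: (protein, 0-based index), motif fully inside the
    # protein and no two slots within 4 residues of each other
    slots = [
        (pi, i)
        for pi, s in enumerate(seqs)
        for i in range(2, len(s) - 2)
    ]
    if len(slots) < config.n_positives:
        raise SyntheticError(
            f"cannot place {config.n_positives} sites in {len(slots)} candidate slots"
        )
    order = rng.permutation(len(slots))
    taken: dict[int, list[int]] = {}
    planted: list[tuple[int, int]] = []
    for oi in order:
        pi, i = slots[oi]
        if any(abs(i - j) < 5 for j in taken.get(pi, ())):
            continue
        taken.setdefault(pi, []).append(i)
        planted.append((pi, i))
        if len(planted) == config.n_positives:
            break
    if len(planted) < config.n_positives:
        raise SyntheticError(
            f"could only place {len(planted)} of {config.n_positives} sites; "
            "increase protein count or lengths"
        )
    planted.sort()

    consensus_mask = rng.random(config.n_positives) >= config.nonconsensus_fraction
    non_e = [a for a in letters if a not in ("E", "K")]
    non_psi = [a for a in letters if a not in PSI_RESIDUES and a != "K"]
    for (pi, i), consensus in zip(planted, consensus_mask):
        s = seqs[pi]
        s[i] = "K"
        if consensus:
            s[i - 1] = PSI_RESIDUES[int(rng.integers(len(PSI_RESIDUES)))]
            s[i + 2] = "E"
        else:
            # explicitly break the consensus context
            if s[i - 1] in PSI_RESIDUES and s[i + 2] == "E":
                s[i + 2] = non_e[int(rng.integers(len(non_e)))]

    planted_set = {(pi, i) for pi, i in planted}
    if config.clean_negatives:
        protected: set[tuple[int, int]] = set()
        for pi, i in planted:
            for off in (-1, 0, 1, 2):
                protected.add((pi, i + off))
        for pi, s in enumerate(seqs):
            for i, c in enumerate(s):
                if c != "K" or (pi, i) in planted_set:
                    continue
                if _has_consensus("".join(s[max(0, i - 1): i + 3]), min(i, 1)):
                    if (pi, i + 2) not in protected:
                        s[i + 2] = non_e[int(rng.integers(len(non_e)))]
                    elif (pi, i - 1) not in protected:
                        s[i - 1] = non_psi[int(rng.integers(len(non_psi)))]
                    # both neighbours protected (overlapping planted sites):
                    # leave it — rare and harmless

    proteins = [
        ProteinRecord(id=f"SYN{pi + 1:05d}", sequence="".join(s))
        for pi, s in enumerate(seqs)
    ]
    positive_annotations = [
        SiteAnnotation(protein_id=proteins[pi].id, position=i + 1, label=POSITIVE)
        for pi, i in planted
    ]
    all_sites = []
    for pi, prot in enumerate(proteins):
        for i, c in enumerate(prot.sequence):
            if c == "K":
                label = POSITIVE if (pi, i) in planted_set else NEGATIVE
                all_sites.append(SiteAnnotation(prot.id, i + 1, label))
    return Proteome(
        proteins=proteins,
        positive_annotations=positive_annotations,
        all_sites=all_sites,
        config=config,
    )


def write_fixture(proteome: Proteome, directory: str | Path) -> dict[str, Path]:
    """Write FASTA + site TSV + fragment lists in the dialects the
    dataset loaders read (round-trip safe)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": directory / "proteins.fasta",
        "sites": directory / "sites.tsv",
        "positive_fragments": directory / "positive_fragments.txt",
        "negative_fragments": directory / "negative_fragments.txt",
    }
    write_fasta(proteome.proteins, paths["fasta"])
    write_site_table(proteome.all_sites, paths["sites"])
    ds = build_candidate_set(proteome.proteins, proteome.positive_annotations)
    write_fragment_list(ds.positives, paths["positive_fragments"])
    write_fragment_list(ds.negatives, paths["negative_fragments"])
    return paths
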