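"""Peptide x HLA two-dimensional interaction maps.

Each map cell (i, j) holds the pairwise interaction energy between peptide
residue i and HLA residue j, looked up in an :class:`EnergyMatrix`.  The HLA
axis has a fixed length of 183 residues; shorter sequences are right-padded
with a neutral token ('X', energy 0 against everything) and longer ones are
truncated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .contact_potential import AA_INDEX, AMINO_ACIDS, EnergyMatrix
from .errors import AlleleError, AlphabetError

HLA_LENGTH = 183
PAD_TOKEN = "X"

_ALLELE_RE = re.compile(r"^HLA-([AB])[*]?")


@dataclass(frozen=True)
class PeptideSequence:
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) not in (9, 10):
            raise AlphabetError(f"peptide length must be 9 or 10, got {len(self.residues)}")
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise AlphabetError(f"invalid peptide characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class HLASequence:
    allele: str
    locus: str  # "A" | "B"
    residues: str  # exactly 183 characters (padded/truncated)


@dataclass
class InteractionMap:
    values: np.ndarray  # (len(peptide), 183)
    peptide: PeptideSequence
    allele: str


def parse_locus(allele: str) -> str:
    m = _ALLELE_RE.match(allele)
    if m is None:
        raise AlleleError(f"cannot parse locus from allele name {allele!r}")
    return m.group(1)


def prepare_hla(allele: str, sequence: str) -> HLASequence:
    """Normalize an HLA sequence to the fixed encoder length of 183.

    Shorter sequences are right-padded with the neutral token; longer ones
    keep their first 183 residues.
    """
    if not sequence:
        raise AlphabetError("empty HLA sequence")
    bad = set(sequence) - set(AMINO_ACIDS)
    if bad:
        raise AlphabetError(f"invalid HLA characters: {sorted(bad)}")
    locus = parse_locus(allele)
    if len(sequence) >= HLA_LENGTH:
        residues = sequence[:HLA_LENGTH]
    else:
        residues = sequence + PAD_TOKEN * (HLA_LENGTH - len(sequence))
    return HLASequence(allele=allele, locus=locus, residues=residues)


def encode(peptide: PeptideSequence, hla: HLASequence, energy: EnergyMatrix) -> InteractionMap:
    """Build the (P, 183) interaction map: values[i, j] = E[peptide[i], hla[j]]."""
    # vectorized lookup; pad token handled via an augmented 21-row/col table
    table = np.zeros((21, 21))
    table[:20, :20] = energy.values
    pep_idx = np.array([AA_INDEX[a] for a in peptide.residues])
    hla_idx = np.array([AA_INDEX.get(a, 20) for a in hla.residues])
    values = table[np.ix_(pep_idx, hla_idx)]
    return InteractionMap(values=values, peptide=peptide, allele=hla.allele)


def sum_preference_score(imap: InteractionMap) -> float:
    """Sum of all map entries; callers rank ascending (lower = more binder-like)."""
    return float(imap.values.sum())
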