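"""Amino-acid interaction preferences derived from residue contacts in protein structures.

The pipeline is: parse PDB text into per-chain residue coordinates, tally
residue-residue contacts under a distance cutoff (either between Calpha atoms
or between any atom pair), convert the pooled contact counts into a symmetric
20x20 log-odds energy matrix, and optionally derive permuted / null control
matrices from it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ConfigError, DegenerateCounts, EmptyStructure, ParseError

logger = logging.getLogger(__name__)

#: Canonical one-letter amino-acid alphabet (fixed ordering used by all matrices).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}

CALPHA_CUTOFF = 6.5  # Angstrom, Calpha-Calpha
ALLATOM_CUTOFF = 4.5  # Angstrom, closest atom pair
CALPHA_EXCLUSION = 1  # skip |i - j| <= 1 in calpha mode
ALLATOM_EXCLUSION = 2  # skip |i - j| <= 2 in all-atom mode


@dataclass
class Residue:
    index: int  # 1-based author sequence index
    name: str  # one-letter code
    ca: np.ndarray  # (3,) Calpha coordinate
    atoms: np.ndarray  # (n_atoms, 3) all atom coordinates incl. Calpha


@dataclass
class ResidueStructure:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ContactCounts:
    counts: np.ndarray  # (20, 20) symmetric nonnegative integers
    mode: str  # "calpha" | "allatom"
    n_structures: int


@dataclass
class EnergyMatrix:
    values: np.ndarray  # (20, 20) symmetric, finite
    variant: str  # "calpha" | "allatom" | "permuted" | "null" | "loaded"
    seed: int | None = None

    def lookup(self, a: str, b: str) -> float:
        """Energy for residue pair (a, b); padding token 'X' is neutral (0)."""
        if a == "X" or b == "X":
            return 0.0
        return float(self.values[AA_INDEX[a], AA_INDEX[b]])


def _parse_atom_line(line: str, lineno: int) -> tuple[str, str, str, int, str, np.ndarray]:
    try:
        atom_name = line[12:16].strip()
        altloc = line[16]
        resname = line[17:20].strip()
        chain = line[21]
        resseq = int(line[22:26])
        xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"malformed ATOM record at line {lineno}: {line.rstrip()!r}") from exc
    return atom_name, altloc, resname, resseq, chain, xyz


def parse_structure(pdb_text: str, chain: str | None = None) -> ResidueStructure:
    """Parse the ATOM records of one chain from PDB-format text.

    Only the first model is read; for alternate locations only the first
    (blank or 'A') is retained; non-canonical residues and residues lacking
    a Calpha atom are skipped with a warning.  ``chain=None`` selects the
    first chain encountered.

    Raises
    ------
    EmptyStructure
        if no canonical residue with a Calpha survives.
    ParseError
        on a malformed coordinate field, naming the line.
    """
    chains = parse_all_chains(pdb_text)
    if chain is None:
        return chains[0]
    for c in chains:
        if c.chain_id == chain:
            return c
    raise EmptyStructure(f"chain {chain!r} not found or empty")


def parse_all_chains(pdb_text: str) -> list[ResidueStructure]:
    """Parse every chain in the first model; see :func:`parse_structure`."""
    # residues keyed per chain by resseq; atoms accumulated in file order
    per_chain: dict[str, dict[int, dict]] = {}
    chain_order: list[str] = []
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6]
        if rec in ("ENDMDL", "END   ") or rec.strip() == "ENDMDL":
            break  # first model only
        if rec != "ATOM  ":
            continue
        atom_name, altloc, resname, resseq, ch, xyz = _parse_atom_line(line, lineno)
        if altloc not in (" ", "A"):
            continue  # first alternate location only
        if resname not in THREE_TO_ONE:
            logger.warning("skipping non-canonical residue %s at line %d", resname, lineno)
            continue
        if ch not in per_chain:
            per_chain[ch] = {}
            chain_order.append(ch)
        res = per_chain[ch].setdefault(
            resseq, {"name": THREE_TO_ONE[resname], "ca": None, "atoms": []}
        )
        if atom_name == "CA" and res["ca"] is None:
            res["ca"] = xyz
        res["atoms"].append(xyz)

    structures: list[ResidueStructure] = []
    for ch in chain_order:
        residues = []
        for resseq in sorted(per_chain[ch]):
            r = per_chain[ch][resseq]
            if r["ca"] is None:
                logger.warning("chain %s residue %d has no Calpha; skipped", ch, resseq)
                continue
            residues.append(
                Residue(index=resseq, name=r["name"], ca=r["ca"], atoms=np.array(r["atoms"]))
            )
        if residues:
            structures.append(ResidueStructure(chain_id=ch, residues=residues))
    if not structures:
        raise EmptyStructure("no canonical residues with Calpha atoms found")
    return structures


def contact_pairs(struct: ResidueStructure, mode: str) -> list[tuple[int, int]]:
    """Residue index pairs (i < j) in spatial contact.

    ``calpha``: Calpha-Calpha distance <= 6.5 A, excluding |i - j| <= 1.
    ``allatom``: minimum any-atom distance <= 4.5 A, excluding |i - j| <= 2.
    """
    if mode == "calpha":
        cutoff, exclusion = CALPHA_CUTOFF, CALPHA_EXCLUSION
    elif mode == "allatom":
        cutoff, exclusion = ALLATOM_CUTOFF, ALLATOM_EXCLUSION
    else:
        raise ConfigError(f"unknown contact mode: {mode!r}")
    if not struct.residues:
        raise EmptyStructure("contact_pairs requires a non-empty structure")

    residues = struct.residues
    pairs: list[tuple[int, int]] = []
    if mode == "calpha":
        coords = np.array([r.ca for r in residues])
        dist = cdist(coords, coords)
        for a in range(len(residues)):
            for b in range(a + 1, len(residues)):
                i, j = residues[a].index, residues[b].index
                if abs(i - j) <= exclusion:
                    continue
                if dist[a, b] <= cutoff:
                    pairs.append((min(i, j), max(i, j)))
    else:
        for a in range(len(residues)):
            for b in range(a + 1, len(residues)):
                i, j = residues[a].index, residues[b].index
                if abs(i - j) <= exclusion:
                    continue
                if cdist(residues[a].atoms, residues[b].atoms).min() <= cutoff:
                    pairs.append((min(i, j), max(i, j)))
    return pairs


def count_contacts(structures: Iterable[ResidueStructure], mode: str) -> ContactCounts:
    """Aggregate contact tallies by residue-type pair over structures."""
    structures = list(structures)
    if not structures:
        raise EmptyStructure("count_contacts requires at least one structure")
    counts = np.zeros((20, 20), dtype=np.int64)
    for struct in structures:
        by_index = {r.index: r for r in struct.residues}
        for i, j in contact_pairs(struct, mode):
            a = AA_INDEX[by_index[i].name]
            b = AA_INDEX[by_index[j].name]
            counts[a, b] += 1
            if a != b:
                counts[b, a] += 1
    return ContactCounts(counts=counts, mode=mode, n_structures=len(structures))


def energy_matrix(counts: ContactCounts) -> EnergyMatrix:
    """Quasi-chemical log-odds energies from contact counts.

    e(a, b) = -ln( p(a, b) / (f(a) * f(b)) ), with p the normalized
    (symmetric) count matrix and f its marginals.  Residue types absent from
    every contact get an all-zero row/column (imputed, warned).  Pairs never
    observed despite positive marginals are imputed with the largest finite
    energy (least preferred), keeping the matrix finite.
    """
    c = counts.counts.astype(float)
    total = c.sum()
    if total <= 0:
        raise DegenerateCounts("zero total contacts")
    p = c / total
    f = p.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = -np.log(p / np.outer(f, f))

    absent = f == 0
    if absent.any():
        logger.warning(
            "residue types with no contacts imputed to 0: %s",
            "".join(aa for aa, m in zip(AMINO_ACIDS, absent) if m),
        )
    unseen = (p == 0) & ~np.isfinite(e)
    finite = e[np.isfinite(e)]
    cap = float(finite.max()) if finite.size else 0.0
    e[unseen] = cap
    e[absent, :] = 0.0
    e[:, absent] = 0.0
    e = (e + e.T) / 2.0  # symmetrize away float round-off
    return EnergyMatrix(values=e, variant=counts.mode)


def control_matrix(base: EnergyMatrix, kind: str, seed: int = 0) -> EnergyMatrix:
    """Permuted or null control variants of an energy matrix.

    ``permuted`` shuffles the multiset of upper-triangle entries (seeded) and
    mirrors back to symmetry; ``null`` is the all-zero map.
    """
    if not np.all(np.isfinite(base.values)):
        raise ConfigError("base matrix must be finite")
    if kind == "null":
        return EnergyMatrix(values=np.zeros((20, 20)), variant="null")
    if kind == "permuted":
        rng = np.random.default_rng(seed)
        iu = np.triu_indices(20)
        entries = base.values[iu].copy()
        rng.shuffle(entries)
        out = np.zeros((20, 20))
        out[iu] = entries
        out = out + out.T - np.diag(np.diag(out))
        return EnergyMatrix(values=out, variant="permuted", seed=seed)
    raise ConfigError(f"unknown control kind: {kind!r}")


def save_energy_matrix(matrix: EnergyMatrix, path: str) -> None:
    """Write a 21x21 TSV (header row/column of one-letter codes); bit-exact round-trip."""
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(AMINO_ACIDS) + "\n")
        for i, aa in enumerate(AMINO_ACIDS):
            row = "\t".join(np.format_float_positional(v, unique=True) for v in matrix.values[i])
            fh.write(f"{aa}\t{row}\n")


def load_energy_matrix(path: str) -> EnergyMatrix:
    """Read a 21x21 TSV written by :func:`save_energy_matrix` (variant='loaded')."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = header[1:]
        if sorted(cols) != sorted(AMINO_ACIDS):
            raise ParseError(f"bad energy-matrix header in {path}")
        values = np.zeros((20, 20))
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 21:
                raise ParseError(f"bad energy-matrix row at line {lineno} of {path}")
            r = AA_INDEX[parts[0]]
            for col, v in zip(cols, parts[1:]):
                values[r, AA_INDEX[col]] = float(v)
    if not np.allclose(values, values.T):
        raise ParseError(f"energy matrix in {path} is not symmetric")
    return EnergyMatrix(values=values, variant="loaded")
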