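"""Mutant-peptide enumeration, binder calling, and neoantigen-load labelling.

Nonsynonymous mutations yield every k-mer window of the mutated protein that
covers the mutated position; each candidate peptide is scored against every
patient HLA allele by the binding model; the per-sample load is the number
of distinct mutant peptides predicted to bind at least one allele.  Two
thresholds coexist by design: resistance uses a strict > 70 load (with no
clinical benefit), survival-style grouping uses load >= 70.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cnn_binding import BindingModel, predict_proba
from .contact_potential import EnergyMatrix
from .errors import ConfigError, ReferenceMismatch
from .interaction_encoder import HLASequence, PeptideSequence, encode

logger = logging.getLogger(__name__)

RESISTANCE_LOAD_THRESHOLD = 70  # strict >, combined with absence of benefit
GROUPING_LOAD_THRESHOLD = 70  # inclusive >=, high/low split
BINDER_PROBABILITY = 0.5  # inclusive >=


@dataclass
class MutationRecord:
    sample: str
    gene: str
    protein_position: int  # 1-based
    ref: str
    alt: str
    mutation_class: str  # "missense" | "synonymous" | "indel"
    sift_damaging: bool = False
    provean_deleterious: bool = False

    def __post_init__(self) -> None:
        if self.protein_position < 1:
            raise ValueError(f"position must be >= 1, got {self.protein_position}")
        if self.mutation_class == "missense" and self.ref == self.alt:
            raise ValueError("missense mutation requires ref != alt")

    @property
    def is_functional(self) -> bool:
        """Damaging by SIFT and simultaneously deleterious by PROVEAN."""
        return bool(self.sift_damaging and self.provean_deleterious)


@dataclass
class BinderCall:
    peptide: str
    allele: str
    probability: float
    binder: bool


def mutant_peptides(protein: str, mutation: MutationRecord, k: int) -> list[str]:
    """All k-mer windows of the mutated protein containing the mutated position."""
    if k not in (9, 10):
        raise ConfigError(f"peptide length must be 9 or 10, got {k}")
    if mutation.mutation_class != "missense":
        raise ConfigError(
            f"mutant_peptides handles missense substitutions, got {mutation.mutation_class!r}"
        )
    pos = mutation.protein_position
    L = len(protein)
    if pos > L:
        raise ValueError(f"position {pos} beyond protein length {L}")
    if protein[pos - 1] != mutation.ref:
        raise ReferenceMismatch(
            f"sample {mutation.sample} gene {mutation.gene}: protein has "
            f"{protein[pos - 1]} at {pos}, expected {mutation.ref}"
        )
    mutated = protein[:pos - 1] + mutation.alt + protein[pos:]
    start_lo = max(1, pos - k + 1)
    start_hi = min(pos, L - k + 1)
    return [mutated[s - 1:s - 1 + k] for s in range(start_lo, start_hi + 1)]


def call_binders(peptides: list[str], alleles: list[HLASequence],
                 models: dict[tuple[str, int], BindingModel],
                 energy: EnergyMatrix) -> list[BinderCall]:
    """Score every peptide x allele combination; binder iff probability >= 0.5.

    Combinations whose (locus, length) key has no model are skipped with a
    warning.
    """
    calls: list[BinderCall] = []
    missing: set[tuple[str, int]] = set()
    for pep in peptides:
        peptide = PeptideSequence(pep)
        for hla in alleles:
            key = (hla.locus, len(peptide))
            model = models.get(key)
            if model is None:
                missing.add(key)
                continue
            imap = encode(peptide, hla, energy)
            prob = float(predict_proba(model, imap.values)[0])
            calls.append(BinderCall(
                peptide=pep, allele=hla.allele, probability=prob,
                binder=prob >= BINDER_PROBABILITY,
            ))
    for key in sorted(missing):
        logger.warning("no model for key %s; combinations skipped", key)
    return calls


def neoantigen_load(calls_by_sample: dict[str, list[BinderCall]]) -> pd.Series:
    """Per-sample count of distinct mutant peptides binding >= 1 allele."""
    loads = {
        sample: len({c.peptide for c in calls if c.binder})
        for sample, calls in calls_by_sample.items()
    }
    return pd.Series(loads, name="neoantigen_load", dtype=int)


def assign_groups(loads: pd.Series, benefit: pd.Series | None = None,
                  threshold: int = RESISTANCE_LOAD_THRESHOLD) -> pd.DataFrame:
    """LoadTable with high/low grouping and resistance labels.

    ``group`` is "high" iff load >= threshold (survival-style split);
    ``resistant`` is True iff load > threshold strictly AND clinical benefit
    is False.  Samples without benefit information get resistant = NA.
    """
    if threshold <= 0:
        raise ConfigError("threshold must be positive")
    table = pd.DataFrame({"neoantigen_load": loads})
    table["group"] = np.where(loads >= threshold, "high", "low")
    if benefit is not None:
        benefit = benefit.reindex(loads.index)
        table["benefit"] = benefit
        resistant = ((loads > threshold) & (benefit == False)).astype("boolean")  # noqa: E712
        resistant[benefit.isna()] = pd.NA
        table["resistant"] = resistant
    return table


def load_pipeline(mutations: list[MutationRecord], proteins: dict[str, str],
                  hla_by_sample: dict[str, list[HLASequence]],
                  models: dict[tuple[str, int], BindingModel],
                  energy: EnergyMatrix,
                  lengths: tuple[int, ...] = (9, 10)) -> tuple[pd.Series, pd.DataFrame]:
    """End-to-end: mutations -> peptides -> binder calls -> per-sample load.

    9-mer and 10-mer calls are pooled into one load per sample.  Samples
    without HLA alleles are excluded with a warning.  Returns (loads,
    per-call table).
    """
    calls_by_sample: dict[str, list[BinderCall]] = {}
    rows = []
    for mut in mutations:
        if mut.mutation_class != "missense":
            continue
        alleles = hla_by_sample.get(mut.sample)
        if not alleles:
            logger.warning("sample %s has no HLA alleles; excluded", mut.sample)
            continue
        protein = proteins.get(mut.gene)
        if protein is None:
            logger.warning("no protein sequence for gene %s; skipped", mut.gene)
            continue
        peptides: list[str] = []
        for k in lengths:
            if len(protein) >= k:
                peptides.extend(mutant_peptides(protein, mut, k))
        calls = call_binders(sorted(set(peptides)), alleles, models, energy)
        calls_by_sample.setdefault(mut.sample, []).extend(calls)
        for c in calls:
            rows.append({"sample": mut.sample, "gene": mut.gene, "peptide": c.peptide,
                         "allele": c.allele, "probability": c.probability,
                         "binder": c.binder})
    loads = neoantigen_load(calls_by_sample)
    return loads, pd.DataFrame(
        rows, columns=["sample", "gene", "peptide", "allele", "probability", "binder"]
    )
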