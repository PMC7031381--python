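"""Seeded generators with known planted signal.

Three families of fixtures:

* binding datasets — random peptides whose binder probability depends on
  anchor-position motifs, with IC50 values straddling the 500 nM boundary;
* cohorts — samples with planted resistance genes whose functional mutations
  raise resistance odds, label-independent synonymous mutations, neoantigen
  loads, and immune-marker expression correlated with load;
* idealized backbone structures (helix / extended) for contact counting.

Every generator is a pure function of its spec plus seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contact_potential import (
    AMINO_ACIDS,
    THREE_TO_ONE,
    EnergyMatrix,
    Residue,
    ResidueStructure,
)
from .errors import ConfigError
from .interaction_encoder import (
    HLASequence,
    PeptideSequence,
    encode,
    prepare_hla,
)
from .cnn_binding import TrainingSet, label_from_affinity

#: immune marker genes grouped as in the immune-score definition
IMMUNE_MARKERS = {
    "cytolytic": ["GZMA", "GZMB", "PRF1", "GNLY"],
    "hla": ["HLA-A", "HLA-B", "HLA-C", "HLA-E", "HLA-F", "HLA-G", "HLA-H",
            "HLA-DMA", "HLA-DMB", "HLA-DOA", "HLA-DOB", "HLA-DPA1", "HLA-DPB1",
            "HLA-DQA1", "HLA-DQA2", "HLA-DQB1", "HLA-DRA", "HLA-DRB1"],
    "ifng": ["IFNG", "IFNGR1", "IFNGR2", "IRF1", "STAT1", "PSMB9"],
    "chemokine": ["CCR5", "CCL3", "CCL4", "CCL5", "CXCL9", "CXCL10", "CXCL11"],
    "adhesion": ["ICAM1", "ICAM2", "ICAM3", "ICAM4", "ICAM5", "VCAM1"],
}
ALL_MARKERS = [g for group in IMMUNE_MARKERS.values() for g in group]


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class MotifSpec:
    """Planted anchor motif controlling binder labels.

    An anchor "matches" when the peptide residue at that position is
    energetically preferred against the HLA residue at the anchor's contact
    column: pair energy at or below the ``preferred_quantile`` of all energy
    matrix entries.  When ``preferred`` is given explicitly it overrides the
    energy-derived sets (same residues for every allele).

    ``label_basis="match"``: each matched anchor adds ``effect`` to the
    binder log-odds.  ``label_basis="energy"``: the log-odds decrease
    linearly with the (batch-standardized) sum of true anchor-cell
    energies, i.e. energetically favourable anchors drive binding
    directly.  ``interaction="xor"``: the log-odds gain the full effect iff
    exactly one of the two anchor groups (first half vs second half of the
    anchor list) is favourable, and only ``xor_both_weight`` of it when both
    are — a position-specific, non-additive rule: any additive score ranks
    the both-favourable class highest, which is wrong here.
    """

    anchor_positions: tuple[int, ...] = (2, 9)  # 1-based peptide positions
    contact_columns: tuple[int, ...] = (30, 150)  # 1-based HLA columns per anchor
    preferred: dict[int, str] = field(default_factory=dict)  # position -> residues
    preferred_quantile: float = 0.2
    effect: float = 3.0
    background_rate: float = 0.1
    interaction: str = "additive"  # "additive" | "xor"
    label_basis: str = "match"  # "match" | "energy"
    xor_both_weight: float = 0.5  # fraction of effect when both groups match

    def __post_init__(self) -> None:
        if self.effect < 0:
            raise ConfigError("motif effect size must be >= 0")
        if not 0 < self.background_rate < 1:
            raise ConfigError("background binder rate must be in (0, 1)")
        if self.interaction not in ("additive", "xor"):
            raise ConfigError(f"unknown interaction kind {self.interaction!r}")
        if len(self.contact_columns) != len(self.anchor_positions):
            raise ConfigError("one contact column per anchor position required")
        if not 0 < self.preferred_quantile < 1:
            raise ConfigError("preferred_quantile must be in (0, 1)")
        if self.label_basis not in ("match", "energy"):
            raise ConfigError(f"unknown label basis {self.label_basis!r}")


def default_motif(length: int = 9, preferred_quantile: float = 0.2,
                  effect: float = 3.0, background_rate: float = 0.1,
                  interaction: str = "additive") -> MotifSpec:
    """Match-basis motif anchored at position 2 and the final position."""
    return MotifSpec(
        anchor_positions=(2, length),
        contact_columns=(30, 150),
        preferred_quantile=preferred_quantile,
        effect=effect,
        background_rate=background_rate,
        interaction=interaction,
    )


def benchmark_motif(length: int = 9, effect: float = 15.0,
                    background_rate: float = 0.5,
                    interaction: str = "additive") -> MotifSpec:
    """Energy-basis benchmark motif: every peptide position anchors to its
    own HLA contact column in the first half of the HLA axis (compatible
    with half-window models); strong effect, near-balanced classes."""
    return MotifSpec(
        anchor_positions=tuple(range(1, length + 1)),
        contact_columns=tuple(10 * (i + 1) for i in range(length)),
        effect=effect,
        background_rate=background_rate,
        interaction=interaction,
        label_basis="energy",
    )


def _preferred_residues(motif: MotifSpec, energy: EnergyMatrix,
                        hla: HLASequence) -> dict[int, str]:
    """Per-anchor preferred residue sets for one allele.

    Explicit sets take precedence; otherwise the residues whose true pair
    energy against the HLA residue at the anchor's contact column falls at
    or below the global ``preferred_quantile`` of all matrix entries (at
    least one residue, the argmin, is always preferred).
    """
    tau = float(np.quantile(energy.values, motif.preferred_quantile))
    out = {}
    for pos, col in zip(motif.anchor_positions, motif.contact_columns):
        if pos in motif.preferred:
            out[pos] = motif.preferred[pos]
            continue
        target = hla.residues[col - 1]
        energies = np.array([energy.lookup(aa, target) for aa in AMINO_ACIDS])
        mask = energies <= tau
        if not mask.any():
            mask[np.argmin(energies)] = True
        out[pos] = "".join(aa for aa, m in zip(AMINO_ACIDS, mask) if m)
    return out


@dataclass
class BindingData:
    training: TrainingSet
    table: pd.DataFrame  # peptide, allele, affinity_nM, label
    peptides: list[PeptideSequence]
    hlas: list[HLASequence]
    seed: int


def gen_binding_data(n: int, motif: MotifSpec, hla_pool: list[HLASequence],
                     energy: EnergyMatrix, seed: int = 0,
                     peptide_length: int = 9,
                     encode_energy: EnergyMatrix | None = None) -> BindingData:
    """Peptides drawn uniformly; binder log-odds set by the planted motif;
    IC50 drawn log-uniform on (10, 500) nM for binders, (500, 50000) otherwise.

    Labels always derive from the true ``energy`` matrix; the interaction
    maps are encoded with ``encode_energy`` when given (e.g. a permuted
    control), so identical data can be re-encoded under control matrices.
    """
    if n < 10:
        raise ConfigError("need n >= 10")
    if not hla_pool:
        raise ConfigError("empty HLA pool")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    seqs = ["".join(row) for row in aa[rng.integers(0, 20, size=(n, peptide_length))]]
    hla_choice = rng.integers(0, len(hla_pool), size=n)

    base = _logit(motif.background_rate)
    if motif.label_basis == "energy":
        # favourable (low) true energies at the anchor cells raise binding odds
        def anchor_signal(pairs):
            zr = np.zeros(n)
            for pos, col in pairs:
                zr -= np.array([
                    energy.lookup(s[pos - 1], hla_pool[c].residues[col - 1])
                    for s, c in zip(seqs, hla_choice)
                ])
            spread = max(float(zr.std()), 1e-12)
            return (zr - zr.mean()) / spread

        pairs = list(zip(motif.anchor_positions, motif.contact_columns))
        if motif.interaction == "additive":
            logits = base + motif.effect * anchor_signal(pairs)
        else:  # non-additive rule over the two anchor groups
            half = max(1, len(pairs) // 2)
            one = anchor_signal(pairs[:half]) > 0
            two = anchor_signal(pairs[half:]) > 0
            logits = base + motif.effect * (
                (one ^ two) + motif.xor_both_weight * (one & two)
            )
    else:
        preferred_by_allele = [_preferred_residues(motif, energy, h) for h in hla_pool]
        matches = np.zeros(n, dtype=int)
        for pos in motif.anchor_positions:
            matches += np.array([
                s[pos - 1] in preferred_by_allele[c][pos]
                for s, c in zip(seqs, hla_choice)
            ], dtype=int)
        if motif.interaction == "additive":
            logits = base + motif.effect * matches
        else:  # xor: boost iff exactly one anchor matches
            logits = base + np.where(matches == 1, motif.effect, -motif.effect)
    labels = (rng.random(n) < _logistic(logits)).astype(int)

    log_ic50 = np.where(
        labels == 1,
        rng.uniform(np.log(10.0), np.log(500.0), size=n),
        rng.uniform(np.log(500.0), np.log(50000.0), size=n),
    )
    affinity = np.exp(log_ic50)
    # numerical guard: keep affinities strictly on the correct side of 500
    affinity = np.where(labels == 1, np.minimum(affinity, 499.999), np.maximum(affinity, 500.0))

    peptides = [PeptideSequence(s) for s in seqs]
    hlas = [hla_pool[i] for i in hla_choice]
    enc = energy if encode_energy is None else encode_energy
    X = np.stack([encode(p, h, enc).values for p, h in zip(peptides, hlas)])
    y = np.array([label_from_affinity(a) for a in affinity])
    table = pd.DataFrame({
        "peptide": seqs,
        "allele": [h.allele for h in hlas],
        "affinity_nM": affinity,
        "label": y,
    })
    locus = hla_pool[0].locus
    return BindingData(
        training=TrainingSet(X=X, y=y, key=(locus, peptide_length)),
        table=table, peptides=peptides, hlas=hlas, seed=seed,
    )


def gen_hla_pool(n: int, seed: int = 0, locus: str = "A") -> list[HLASequence]:
    """Random fixed-length HLA sequences with parseable allele names."""
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    pool = []
    for i in range(n):
        seq = "".join(aa[rng.integers(0, 20, size=183)])
        pool.append(prepare_hla(f"HLA-{locus}*{i + 1:02d}:01", seq))
    return pool


@dataclass
class CohortSpec:
    n_samples: int = 120
    n_genes: int = 100
    n_planted: int = 5
    odds_ratio: float = 8.0
    background_functional_rate: float = 0.1
    synonymous_rate: float = 0.1
    resistant_fraction: float = 0.4
    evader_fraction: float = 0.2
    load_mean_resistant: float = 120.0
    load_mean_sensitive: float = 40.0
    n_background_expr_genes: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.background_functional_rate, self.synonymous_rate,
                  self.resistant_fraction, self.evader_fraction):
            if not 0 < r < 1:
                raise ConfigError("rates and fractions must be in (0, 1)")
        if self.odds_ratio <= 1:
            raise ConfigError("planted odds ratio must exceed 1")
        if self.n_planted > self.n_genes:
            raise ConfigError("more planted genes than genes")
        p0 = self.background_functional_rate
        if self.odds_ratio * p0 / (1 - p0) / (1 + self.odds_ratio * p0 / (1 - p0)) >= 1:
            raise ConfigError("odds ratio pushes mutation probability to 1")


@dataclass
class Cohort:
    samples: list[str]
    genes: list[str]
    planted_genes: list[str]
    mutations: pd.DataFrame  # MAF-like rows, functional + synonymous
    loads: pd.Series  # per-sample neoantigen counts
    benefit: pd.Series  # clinical benefit booleans
    resistant: pd.Series  # ground-truth resistance labels
    evader: pd.Series  # ground-truth immune-evasion labels
    expression: pd.DataFrame  # samples x genes, log2 scale
    spec: CohortSpec

    def records(self) -> list:
        """Mutation rows as :class:`neopred.neoantigen_load.MutationRecord`."""
        from .neoantigen_load import MutationRecord

        return [
            MutationRecord(
                sample=r["sample"], gene=r["gene"],
                protein_position=r["protein_position"], ref=r["ref"],
                alt=r["alt"], mutation_class=r["class"],
                sift_damaging=r["sift_damaging"],
                provean_deleterious=r["provean_deleterious"],
            )
            for r in self.mutations.to_dict("records")
        ]


def gen_cohort(spec: CohortSpec) -> Cohort:
    """Cohort with planted resistance genes and load-correlated immune markers.

    Resistance labels are drawn first; planted genes mutate with the odds of
    the background rate multiplied by ``spec.odds_ratio`` in resistant
    samples.  Synonymous mutations are label-independent.  Immune-marker
    expression increases with neoantigen load except in designated evaders,
    where it is suppressed.
    """
    rng = np.random.default_rng(spec.seed)
    samples = [f"S{i + 1:04d}" for i in range(spec.n_samples)]
    genes = [f"GENE{i + 1:04d}" for i in range(spec.n_genes)]
    planted = genes[:spec.n_planted]

    resistant = rng.random(spec.n_samples) < spec.resistant_fraction
    if resistant.all() or not resistant.any():  # guard tiny cohorts
        resistant[0] = True
        resistant[-1] = False
    benefit = ~resistant

    p0 = spec.background_functional_rate
    odds1 = spec.odds_ratio * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    prob = np.full((spec.n_samples, spec.n_genes), p0)
    planted_cols = np.arange(spec.n_planted)
    prob[np.ix_(resistant, planted_cols)] = p1
    functional = rng.random((spec.n_samples, spec.n_genes)) < prob
    synonymous = rng.random((spec.n_samples, spec.n_genes)) < spec.synonymous_rate

    loads = np.where(
        resistant,
        rng.poisson(spec.load_mean_resistant, spec.n_samples),
        rng.poisson(spec.load_mean_sensitive, spec.n_samples),
    )

    aa = np.array(list(AMINO_ACIDS))
    rows = []
    for cls, matrix in (("missense", functional), ("synonymous", synonymous)):
        sidx, gidx = np.nonzero(matrix)
        positions = rng.integers(5, 500, size=len(sidx))
        refs = aa[rng.integers(0, 20, size=len(sidx))]
        alts = aa[rng.integers(0, 20, size=len(sidx))]
        for s, g, pos, ref, alt in zip(sidx, gidx, positions, refs, alts):
            if cls == "missense" and alt == ref:
                alt = aa[(np.where(aa == ref)[0][0] + 1) % 20]
            if cls == "synonymous":
                alt = ref
            rows.append({
                "sample": samples[s], "gene": genes[g],
                "protein_position": int(pos), "ref": str(ref), "alt": str(alt),
                "class": cls,
                "sift_damaging": cls == "missense",
                "provean_deleterious": cls == "missense",
            })
    mutations = pd.DataFrame(
        rows, columns=["sample", "gene", "protein_position", "ref", "alt",
                       "class", "sift_damaging", "provean_deleterious"],
    )

    # evaders: high-load samples whose immune markers are suppressed
    order = np.argsort(-loads)
    n_evaders = max(1, int(round(spec.evader_fraction * spec.n_samples)))
    evader = np.zeros(spec.n_samples, dtype=bool)
    evader[order[:n_evaders]] = True

    load_z = (loads - loads.mean()) / max(loads.std(), 1e-9)
    expr_genes = ALL_MARKERS + [f"BG{i + 1:04d}" for i in range(spec.n_background_expr_genes)]
    expr = rng.normal(8.0, 1.0, size=(spec.n_samples, len(expr_genes)))
    for j, g in enumerate(expr_genes):
        if g in ALL_MARKERS:
            expr[:, j] += 1.5 * load_z
            expr[evader, j] -= 5.0
    expr = np.maximum(expr, 0.0)

    idx = pd.Index(samples, name="sample")
    return Cohort(
        samples=samples, genes=genes, planted_genes=planted,
        mutations=mutations,
        loads=pd.Series(loads, index=idx, name="neoantigen_load"),
        benefit=pd.Series(benefit, index=idx, name="benefit"),
        resistant=pd.Series(resistant, index=idx, name="resistant"),
        evader=pd.Series(evader, index=idx, name="evader"),
        expression=pd.DataFrame(expr, index=idx, columns=expr_genes),
        spec=spec,
    )


def gen_structure_fixture(n_residues: int, geometry: str = "helix",
                          seed: int = 0) -> ResidueStructure:
    """Ideal-geometry backbone with ~3.8 A consecutive Calpha spacing."""
    if n_residues < 4:
        raise ConfigError("need at least 4 residues")
    if geometry not in ("helix", "extended"):
        raise ConfigError(f"unknown geometry {geometry!r}")
    rng = np.random.default_rng(seed)
    names = [AMINO_ACIDS[i] for i in rng.integers(0, 20, size=n_residues)]
    residues = []
    for i in range(n_residues):
        if geometry == "helix":
            # ideal alpha helix: radius 2.3 A, rise 1.5 A, 100 deg per residue
            theta = np.deg2rad(100.0 * i)
            ca = np.array([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])
        else:
            ca = np.array([3.8 * i, 0.0, 0.0])
        residues.append(Residue(index=i + 1, name=names[i], ca=ca, atoms=ca[None, :]))
    return ResidueStructure(chain_id="A", residues=residues)


def structure_to_pdb(struct: ResidueStructure) -> str:
    """Minimal PDB text (Calpha ATOM records only) for a generated structure."""
    one_to_three = {v: k for k, v in THREE_TO_ONE.items()}
    lines = []
    serial = 1
    for r in struct.residues:
        x, y, z = r.ca
        lines.append(
            f"ATOM  {serial:5d}  CA  {one_to_three[r.name]} {struct.chain_id}"
            f"{r.index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
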