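"""Random-forest classification of therapeutic resistance from mutation status.

Protocol: build a samples x genes binary matrix of functional mutations
(gene kept iff mutated in strictly more than 5% of samples), train a
1000-tree forest under ten-repeat stratified 5-fold cross validation with
vote-ratio scores, rank genes by z-scaled permutation importance (mean
decrease in accuracy), compare against a synonymous-mutation negative
control with a matched feature count, and expand selected genes through a
protein interactome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .cnn_binding import roc_auc
from .errors import (
    ConfigError,
    DegenerateLabels,
    EmptyFeatureSet,
    InsufficientControl,
)
from .neoantigen_load import MutationRecord

logger = logging.getLogger(__name__)

DEFAULT_MIN_FREQ = 0.05
IMPORTANCE_CUTOFF = 3.0


@dataclass
class MutationMatrix:
    values: pd.DataFrame  # samples x genes, {0, 1}
    mutation_class: str  # "functional" | "synonymous"
    min_freq: float

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ForestConfig:
    n_trees: int = 1000
    repeats: int = 10
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ConfigError("n_trees must be >= 1")
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")


@dataclass
class CVResult:
    scores: pd.Series  # out-of-fold vote ratios averaged over repeats
    auc_per_repeat: list[float]
    mean_auc: float


def build_matrix(mutations: list[MutationRecord], mutation_class: str,
                 samples: list[str],
                 min_freq: float = DEFAULT_MIN_FREQ) -> MutationMatrix:
    """Binary mutation-status matrix filtered at a strict frequency threshold.

    ``functional`` keeps records flagged by both SIFT and PROVEAN;
    ``synonymous`` keeps synonymous records.  A gene is retained iff its
    mutated-sample fraction is strictly greater than ``min_freq``.
    """
    if not samples:
        raise ConfigError("samples must be nonempty")
    if mutation_class == "functional":
        kept = [m for m in mutations if m.is_functional]
    elif mutation_class == "synonymous":
        kept = [m for m in mutations if m.mutation_class == "synonymous"]
    else:
        raise ConfigError(f"unknown mutation class {mutation_class!r}")

    status: dict[str, set[str]] = {}
    sample_set = set(samples)
    for m in kept:
        if m.sample in sample_set:
            status.setdefault(m.gene, set()).add(m.sample)
    n = len(samples)
    genes = sorted(g for g, ss in status.items() if len(ss) / n > min_freq)
    if not genes:
        raise EmptyFeatureSet(
            f"no gene exceeds frequency {min_freq} for class {mutation_class!r}"
        )
    values = pd.DataFrame(0, index=pd.Index(samples, name="sample"), columns=genes)
    for g in genes:
        values.loc[sorted(status[g]), g] = 1
    return MutationMatrix(values=values, mutation_class=mutation_class, min_freq=min_freq)


def matched_control(functional: MutationMatrix,
                    mutations: list[MutationRecord]) -> MutationMatrix:
    """Synonymous-mutation matrix with the same gene count as the functional one.

    The frequency threshold is scanned over the observed synonymous gene
    frequencies and the one yielding the count closest to (but not below)
    the target is chosen; any excess genes are trimmed most-frequent-first,
    alphabetical among ties.
    """
    target = len(functional.genes)
    samples = functional.samples
    try:
        full = build_matrix(mutations, "synonymous", samples, min_freq=0.0)
    except EmptyFeatureSet as exc:
        raise InsufficientControl("no synonymous mutations available") from exc
    freqs = full.values.mean(axis=0)
    if len(freqs) < target:
        raise InsufficientControl(
            f"only {len(freqs)} synonymous genes, {target} needed"
        )
    # scan candidate thresholds (just below each observed frequency)
    candidates = sorted(set(freqs.values))
    best_thr, best_count = 0.0, len(freqs)
    for thr in [0.0] + candidates:
        count = int((freqs > thr).sum())
        if count >= target and count <= best_count:
            best_thr, best_count = thr, count
    genes = freqs[freqs > best_thr]
    # trim excess: drop the most frequent genes first, alphabetical among ties
    order = sorted(genes.index, key=lambda g: (-genes[g], g))
    drop = order[:len(genes) - target]
    kept = sorted(set(genes.index) - set(drop))
    return MutationMatrix(
        values=full.values[kept], mutation_class="synonymous", min_freq=best_thr
    )


def _check_labels(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise DegenerateLabels("labels contain a single class")


def cv_rf(matrix: MutationMatrix, labels: pd.Series,
          config: ForestConfig = ForestConfig()) -> CVResult:
    """Repeated stratified k-fold forest CV with out-of-fold vote ratios.

    Vote ratios are averaged over repeats; AUC is reported per repeat and
    as the mean.  Fully deterministic under ``config.seed``.
    """
    X = matrix.values.to_numpy()
    y = labels.reindex(matrix.values.index).to_numpy().astype(int)
    _check_labels(y)
    n = len(y)
    score_sum = np.zeros(n)
    aucs = []
    for rep in range(config.repeats):
        fold_scores = np.zeros(n)
        skf = StratifiedKFold(n_splits=config.folds, shuffle=True,
                              random_state=config.seed * 1000 + rep)
        for train_idx, test_idx in skf.split(X, y):
            rf = RandomForestClassifier(
                n_estimators=config.n_trees,
                random_state=config.seed * 1000 + rep,
                n_jobs=1,
            )
            rf.fit(X[train_idx], y[train_idx])
            pos = list(rf.classes_).index(1)
            fold_scores[test_idx] = rf.predict_proba(X[test_idx])[:, pos]
        aucs.append(roc_auc(fold_scores, y))
        score_sum += fold_scores
    scores = pd.Series(score_sum / config.repeats, index=matrix.values.index,
                       name="vote_ratio")
    return CVResult(scores=scores, auc_per_repeat=aucs, mean_auc=float(np.mean(aucs)))


def loo_scores(matrix: MutationMatrix, labels: pd.Series,
               config: ForestConfig = ForestConfig()) -> pd.Series:
    """Leave-one-sample-out vote ratios (each forest excludes the scored sample)."""
    X = matrix.values.to_numpy()
    y = labels.reindex(matrix.values.index).to_numpy().astype(int)
    _check_labels(y)
    out = np.zeros(len(y))
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        rf = RandomForestClassifier(n_estimators=config.n_trees,
                                    random_state=config.seed, n_jobs=1)
        rf.fit(X[mask], y[mask])
        pos = list(rf.classes_).index(1)
        out[i] = rf.predict_proba(X[i:i + 1])[0, pos]
    return pd.Series(out, index=matrix.values.index, name="vote_ratio")


def variable_importance(matrix: MutationMatrix, labels: pd.Series,
                        config: ForestConfig = ForestConfig(),
                        n_permutations: int = 20) -> pd.Series:
    """Z-scaled permutation importance (mean decrease in accuracy).

    A forest is fit on the full matrix; each feature is permuted
    ``n_permutations`` times and the drop in training accuracy recorded.
    The importance is the mean drop divided by its standard error (0 when
    permutation never changes accuracy).
    """
    X = matrix.values.to_numpy()
    y = labels.reindex(matrix.values.index).to_numpy().astype(int)
    _check_labels(y)
    rf = RandomForestClassifier(n_estimators=config.n_trees,
                                random_state=config.seed, n_jobs=1)
    rf.fit(X, y)
    base_acc = (rf.predict(X) == y).mean()
    rng = np.random.default_rng(config.seed)
    importances = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        drops = np.empty(n_permutations)
        for r in range(n_permutations):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(y)), j]
            drops[r] = base_acc - (rf.predict(Xp) == y).mean()
        se = drops.std(ddof=1) / np.sqrt(n_permutations)
        importances[j] = 0.0 if se == 0 else drops.mean() / se
    return pd.Series(importances, index=matrix.values.columns, name="importance")


def select(importance: pd.Series, cutoff: float = IMPORTANCE_CUTOFF) -> list[str]:
    """Genes with importance strictly greater than the cutoff."""
    return sorted(importance.index[importance > cutoff])


@dataclass
class InteractomeGraph:
    neighbours: dict[str, set[str]] = field(default_factory=dict)

    @classmethod
    def from_edges(cls, edges: list[tuple[str, str]]) -> "InteractomeGraph":
        nb: dict[str, set[str]] = {}
        for a, b in edges:
            if a == b:
                continue  # no self-loops
            nb.setdefault(a, set()).add(b)
            nb.setdefault(b, set()).add(a)
        return cls(neighbours=nb)


def expand_interactome(genes: list[str], graph: InteractomeGraph) -> set[str]:
    """Input genes plus their first-degree interactome neighbours."""
    out = set(genes)
    for g in genes:
        nbrs = graph.neighbours.get(g)
        if nbrs is None:
            logger.info("gene %s absent from interactome", g)
            continue
        out |= nbrs
    return out
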