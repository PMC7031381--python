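# neopred

Tools for predicting peptide–MHC class I binding from structure-derived
amino-acid interaction maps, estimating per-sample neoantigen load, and
classifying therapeutic resistance / immune evasion from functional
mutation profiles.

The stack has seven parts:

| Module | What it does |
| --- | --- |
| `neopred.contact_potential` | Derives a symmetric 20×20 amino-acid interaction-preference (energy) matrix from residue contacts in protein structures (Cα–Cα ≤ 6.5 Å or any-atom ≤ 4.5 Å), plus permuted/null control matrices and TSV round-tripping. |
| `neopred.interaction_encoder` | Builds the 2D peptide × HLA interaction map (P × 183) used as CNN input, and the sum-of-preferences baseline score. |
| `neopred.cnn_binding` | A two-convolution-layer binding classifier in pure numpy: analytic backpropagation, SGD with momentum, per-neuron max-norm constraint, L2 weight + L1 activation penalties, hyperparameter grid search, rank-based AUC / F1 evaluation, and 500 nM binder labelling. |
| `neopred.neoantigen_load` | Enumerates mutant k-mers (9/10) around missense mutations, scores peptide × allele pairs, counts distinct binding peptides per sample, and applies the load-70 resistance / grouping rules. |
| `neopred.resistance_forest` | The random-forest resistance protocol: >5% functional-mutation feature matrices, feature-count-matched synonymous negative controls, ten-repeat stratified 5-fold CV with vote-ratio scores, z-scaled permutation importance (cutoff 3), leave-one-out scoring, and interactome expansion. |
| `neopred.immune_regression` | Geometric-mean immune score, load-correlated marker selection, 70th/30th-percentile evasion labels, min-max parameter scaling, and simple/lasso/elastic-net/ridge regression with CV-selected penalties. |
| `neopred.synthetic_data` | Seeded generators: binding datasets with planted anchor motifs and IC50 values straddling 500 nM, cohorts with planted resistance genes and load-correlated immune markers, and ideal helix/extended structure fixtures. |

`neopred.benchmarks` wires the generators to the analysis modules into the
reference benchmarks (motif recovery vs permuted-map and sum baselines,
negative-control forests, planted-gene recovery) used by the acceptance
tests and the acceptance report.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (convolution and
gradient oracles, max-norm contract, motif recovery, threshold semantics,
negative-control forests, planted-gene recovery, scaling identities, window
enumeration, and bit-level determinism).

## CLI

All commands are grouped under a single entry point:

```sh
neopred potentials --pdb-dir structures/ --mode calpha --out energy.tsv
neopred potentials --pdb-dir structures/ --control permuted --seed 7 --out perm.tsv

neopred train --data binding.tsv --hla-seqs hla.fasta --energy energy.tsv \
              --locus A --length 9 --out model.json
neopred predict --model model.json --peptides peps.fasta --hla-seqs hla.fasta \
                --alleles "HLA-A*02:01" --energy energy.tsv --out scores.tsv

neopred neoload --mutations muts.tsv --proteins proteins.fasta --hla hla.tsv \
                --hla-seqs hla.fasta --model-dir models/ --energy energy.tsv \
                --out load.tsv

neopred resist --mutations muts.tsv --labels labels.tsv --mode functional \
               --trees 1000 --repeats 10 --folds 5 --seed 0 --out results/
neopred immune --expr expression.tsv --loads loads.tsv --out results/
neopred regress --features features.tsv --labels labels.tsv --seed 0 --out report.json

neopred simulate binding --seed 1 --out data/    # also: cohort, structure
```

Input formats are plain text: FASTA for sequences, MAF-like TSV for
mutations (`sample`, `gene`, `protein_change` e.g. `p.A50V`, `class`,
SIFT/PROVEAN flags), TSV tables for affinities, labels, expression, and
edge lists. Energy matrices are 21×21 TSVs (header row/column of one-letter
codes) with bit-exact round-tripping; binding models serialize to JSON.
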