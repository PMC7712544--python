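# epiforest

Iterative random-forest feature reduction and forest-structure epistasis
screening for case-control genotype data.

The pipeline detects gene–gene (and gene–covariate) interactions associated
with a binary clinical outcome in five stages:

1. **Single-variant baseline** — Cochran–Armitage additive trend scan
   (Manhattan-compatible TSV output).
2. **Stage-1 forest screen** — a class-weighted random forest on all
   dosages; per-feature *corrected impurity* importance (each candidacy is
   debited by the impurity gain of a within-node permuted copy, removing the
   allele-frequency bias of raw Gini importance) with mirrored-null
   empirical p-values; features with p < 0.01 advance.
3. **r2VIM consensus selection** — several independent forests; a feature is
   kept only if its permutation importance is at least 1× the magnitude of
   the most negative importance in *every* forest.
4. **Forest-structure epistasis screen** — for every pair of selected
   features: paired selection frequency (exact binomial tail against the
   independence expectation) and selection asymmetry (does one feature
   concentrate under a particular daughter of the other's split, beyond the
   structural opportunity of each side?), Fisher-combined and BH-adjusted;
   pairs that look like linkage disequilibrium (co-occurrence deficit with
   no asymmetry) are labelled and excluded.
5. **Confirmation and networks** — dummy-coded logistic interaction LRTs
   (minimum p over genotype-level combinations, second BH pass), condensation
   of confirmed pairs into connected networks (A|B + A|C → A|B|C), and a
   conditional-inference-style decision tree per network whose terminal
   nodes report case/control counts and odds ratios normalized to the
   overall (or complement) odds of being a case.

A simulation module generates Hardy–Weinberg genotype cohorts with planted
additive effects, planted AND/XOR epistatic pairs, optional LD-block copies,
and a logistic phenotype with the baseline calibrated by bisection to a
target case fraction — so the whole pipeline is testable without external
data.

## CLI

```sh
# generate a synthetic cohort (.tped/.tfam + truth table)
epiforest simulate --spec spec.json --out cohort

# variant filters (MAF >= 0.01, autosomes only) and the GWAS baseline
epiforest filter --tped cohort.tped --tfam cohort.tfam --out filtered
epiforest gwas --tped filtered.tped --tfam filtered.tfam --out gwas.tsv

# the full pipeline from one JSON config
epiforest run-all --config config.json --out results/ --seed 1
```

`run-all` writes per-stage TSVs, the forest JSON, per-network leaf tables /
dot files, and a deterministic `manifest.json` (same seed ⇒ byte-identical
outputs).

The config mirrors `epiforest.PipelineConfig`; defaults reproduce the
reference analysis settings (1000-tree stage-1 forest with mtry 1/3, 11
r2VIM forests of 10,000 trees with 10%-of-cohort node floor and relative
importance threshold 1, FDR 0.05 at both adjustment points). Tests and the
examples below use reduced desk-scale tree counts.

## Library

```python
from epiforest import (SimulationSpec, simulate, PipelineConfig, run_pipeline)

spec = SimulationSpec(n_subjects=2000, n_variants=500,
                      interactions=[(3, 7, "AND", 1.5)],
                      maf_overrides=[(3, 0.3), (7, 0.3)], seed=1)
cfg = PipelineConfig(simulation=spec, stage1_n_trees=300,
                     r2vim_n_forests=5, r2vim_n_trees=300, seed=1)
result = run_pipeline(cfg, "out/")
print(result.screen.retained())
for tree in result.network_trees:
    print(tree.to_outline())
```

## Tests and acceptance

```sh
python -m pytest -q tests/            # unit + property + acceptance suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds the acceptance criteria (exact oracle
equivalence against brute-force computations, importance bias correction,
null-control and planted-pair-recovery pipeline simulations, the class
weighting contract, odds-ratio accounting, end-to-end determinism). The
published headline results of the reference analysis derive from a
controlled-access cohort, so there are no numeric targets to reproduce;
`scripts/acceptance.py` runs a fast self-check of the recomputable
properties and emits an empty JSON target report.
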