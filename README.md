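# heterospot

Comparative two-dimensional gel electrophoresis (2-DE) proteomics of an F1
hybrid and its two inbred parents, built around the question of heterosis:
which proteins does the hybrid express *nonadditively* — away from the
midparent expectation — and in which direction?

The package is aimed at plant proteomics analysts working downstream of gel
image analysis. It takes spot-volume tables (one intensity per spot, gel,
genotype, replicate and developmental stage), and provides:

- **Spot quantification** — per-gel %Vol normalization (each spot as a
  fraction of its gel's total detected volume) and the replicate
  reproducibility rule: a spot counts for a genotype only if detected on
  every replicate gel. Presence/absence patterns (e.g. a spot seen in one
  parent and the hybrid only) are labelled as dominant-inheritance
  signatures.
- **Inheritance-mode classification** — for each spot the midparent value
  MP = (P1 + P2)/2 is computed per replicate. A spot is differentially
  expressed when hybrid and parents separate by fold change > 1.5 at
  t-test p < 0.05 in at least one pairwise contrast. Differential spots
  indistinguishable from MP are *additive*; the rest are graded
  `++` (above high parent), `+` (high parent), `+/-` (partial dominance),
  `-` (low parent), `--` (below low parent) or `D` (different), the
  standard six-mode scheme for hybrid/parent expression surveys.
- **Stage overlap** — dry-seed (DS) vs 24-h-imbibed (24HAI) comparisons
  within a genotype (newly detected / lost / changed spots) and
  reconciliation of mode calls for spots differential at both stages.
- **PMF identification** — peptide mass fingerprinting with in-silico
  tryptic digestion, 25 ppm peak matching, sequence coverage, and a
  MOWSE-style score whose 95% significance threshold is estimated from
  shuffled-sequence decoys; an identification must pass all five classic
  criteria (significant score, ≥4 peptides, >10% coverage, 25 ppm peptide
  and 0.2 Da parent tolerance).
- **Synthetic data** — a simulator that plants known inheritance modes
  (log-normal replicate noise, per-gel detection dropout) and synthetic
  PMF spectra (true tryptic masses with ppm-scale error plus contaminant
  peaks), so every stage of the pipeline can be validated against ground
  truth.

The package also ships the per-mode spot counts, cross-stage overlap
records and grain-weight summaries of a published maize hybrid
(Zong3/87-1) embryo survey as reference fixtures.

## Worked example

```python
from heterospot import (SimulationConfig, classify_table, normalize_volumes,
                        simulate_spot_experiment, summarize_modes)

cfg = SimulationConfig(n_spots=2000, cv=0.1, effect_fold=3.0, seed=42)
table, truth = simulate_spot_experiment(cfg)
results = classify_table(normalize_volumes(table))
print(summarize_modes(results, "DS").pct_nonadditive)
```

Running `python examples/01_simulate_and_classify.py` prints:

```
DS: 155 differential spots of 1256 classified; 82 nonadditive (52.9% of differential)
   per mode: {'++': 7, '+': 13, '+/-': 5, '-': 8, '--': 49}
24HAI: 169 differential spots of 1266 classified; 76 nonadditive (44.97% of differential)
   per mode: {'++': 10, '+': 13, '+/-': 1, '-': 10, '--': 42}
overall agreement with the planted truth: 99.8%
```

i.e. of the simulated spots retained on all replicate gels, 155 separate
hybrid from parents at DS, 82 of those deviate from the midparent, and the
mode calls agree with the planted truth for 99.8% of spots. The other
examples cover the packaged reference tables (`02`), PMF identification
(`03`, printing the match count, coverage, score vs decoy threshold and
the accept/reject verdict), and stage comparisons plus the grain-weight
t-test (`04`).

A thin CLI mirrors the library (`heterospot simulate | normalize |
classify | overlap | pmf | all`); `heterospot all config.yaml` runs the
whole pipeline from a YAML config and writes TSV reports plus a manifest
recording every seed and threshold.

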