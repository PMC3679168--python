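# Methods

## The analysis model

The pipeline operates downstream of 2-DE image analysis: its input is a
long table of spot volumes indexed by spot, stage, genotype (two inbred
parents P1, P2 and their F1 hybrid H) and replicate gel, with an explicit
`detected` flag per observation. Spot correspondence across gels is assumed
given by `spot_id`; correspondence across *stages* is an explicit external
id mapping, because stage gel sets are numbered independently.

**Normalization.** Each detected volume is divided by the summed detected
volume of its own gel (the %Vol convention). Missing spots contribute
nothing to the total. This assumes the total protein signal per gel is
comparable across genotypes; see "Known limitations" for where that
assumption bends.

**Reproducibility rule.** A spot is retained for a genotype and stage only
if detected on all replicate gels there (default three). Retained-set
membership drives both presence-pattern labelling (a spot in one parent and
the hybrid is the classic dominant-inheritance signature) and eligibility
for mode classification (all three genotypes must be retained).

**Differential testing and mode classification.** The midparent value is
the per-replicate mean of the paired parental volumes — the additive
expectation for the hybrid. Four contrasts are computed per spot: H vs MP,
H vs P1, H vs P2, P1 vs P2. Each contrast reports the ratio of group means
(larger/smaller, so ≥ 1), a two-sided two-sample t-test p-value, and a
`significant` flag under the dual rule *fold change > 1.5 and p < 0.05*.
The decision table, evaluated in order:

1. **not differential** unless at least one of the three pairwise genotype
   contrasts passes the dual rule. (The deliberate consequence: a spot can
   be differential purely through a parent–parent difference, which is what
   makes *additive* a large class.)
2. **additive** if H vs MP fails the dual rule.
3. otherwise nonadditive, graded by the hybrid mean's position and the
   parent-wise *p-values alone* (no fold criterion inside the mode table):
   `++` above both parents and significant vs both; `--` below both and
   significant vs both; `+` indistinguishable from the high parent but
   significant vs the low; `-` the mirror image; `+/-` strictly between
   the parents and significant vs both; `D` anything else.

`D` is a residual class by construction: at small replicate noise every
strong, consistent deviation lands in one of the five named branches, so
`D` collects ambiguous intermediate cases (e.g. significant vs MP but vs
neither parent). It cannot be planted deterministically, and recovery
guarantees are therefore stated for the five plantable modes only.

**t-test flavor.** Welch's unequal-variance test is the default (n = 3 per
group, no evidence for equal variances); a pooled-variance switch is
provided (`ttest="pooled"` / `--ttest pooled`). At n = 3 Welch's test is
conservative — its measured null rejection rate is ≈ 0.036 at a nominal
0.05, where the pooled test is calibrated (≈ 0.051 under equal-variance
log-normal noise). Calibration checks therefore exercise the pooled
flavor; the conservative default trades a little power for robustness to
variance heterogeneity. Tests run on the natural scale by default (a
`log` option transforms volumes before testing; fold changes always come
from natural-scale means). Degenerate inputs: when both groups have zero
within-group variance the t statistic is undefined and the p-value is
reported as a sentinel — 1 for equal means, 0 for unequal means — with the
dual significance rule still applied. No multiple-testing correction is
applied by default (per-spot p < 0.05 matches the field's reporting
convention for these surveys); summaries re-derive all percentages from
counts and round to two decimals.

**Stage comparison.** Within a genotype, spots retained at only one stage
are `newly_detected`/`lost`; doubly retained spots get the same dual-rule
contrast between stages (`changed`/`unchanged`). For spots differential at
both stages, overlap records pair the per-stage mode codes and count
same-pattern cases.

## PMF identification

Tryptic digestion cleaves C-terminal to K or R except before P, with 0..k
missed cleavages (default k = 1). Peptide [M+H]+ masses are monoisotopic
residue masses (standard table, Cys unmodified; optional fixed
carbamidomethyl-Cys) plus water (18.010565 Da) and a proton (1.007276 Da).
Peptides shorter than 4 residues or outside 500–5000 Da are excluded from
matching. Each observed peak is assigned to at most one fragment — the
nearest in relative error within the tolerance (default 25 ppm), ties
toward the lower-mass fragment — and each fragment counts once toward the
matched-peptide tally. Coverage is the union of matched fragments' residue
intervals over the protein length.

The score is classic MOWSE: fragment counts over the whole database are
binned by 100 Da peptide mass × 10 kDa intact protein mass and normalized
within each protein-mass column by the column total (so each cell is a
frequency; cells unseen in a column get a sub-minimal pseudo-frequency
1/(column count + 1)). A match set scores
`50000 / (∏ matched-cell frequencies × intact mass in Da)`. Significance
is empirical rather than closed-form: the same peak list is scored against
N shuffled copies of the candidate (default N = 1000, seeded; shuffling
preserves composition and hence intact mass), and the observed score must
exceed the decoy (1 − α) quantile (α = 0.05). An identification is
accepted only when the score is significant, ≥ 4 distinct peptides match,
coverage exceeds 10%, all match errors are within tolerance, and — when an
observed intact mass is supplied — the candidate mass agrees within
0.2 Da. Trypsin autolysis calibrant peaks (2163.333, 2273.434) can be
stripped before matching.

## The synthetic-data generator

The spot simulator emulates the reference design: 3 genotypes × 3
replicate gels × 2 stages. Per stage each spot draws a planted mode from
configurable proportions (default: the reference dry-seed composition,
where ~88% of spots are not differential) and a baseline mean log-uniform
over a 10³ dynamic range (gel intensities are right-skewed and span
orders of magnitude). Genotype means implement the mode with planted
effect fold f (default 3):

- parents sit f-fold apart for `additive` (H at midparent), `++`
  (H = f × high parent) and `--` (H = low parent / f);
- the dominance modes `+`, `-`, `+/-` separate the parents by f² instead.
  A dominance hybrid coincides with (or lies between) its parents, so its
  ratio to the midparent is bounded by 2 and equals 2f/(1+f) — exactly
  1.5 at f = 3, a knife edge against the fold-change rule. With f²
  separation the midparent ratio is 2f²/(1+f²) ≈ 1.8 at the default,
  making the planted call detectable; `+/-` places H at the 25% quantile
  point between the parent means (configurable);
- `D` uses equal parents with H = f × midparent. Under the decision table
  such spots satisfy the `++` branch (above both parents, significant vs
  both), which is why `D` recovery is not asserted — consistent with its
  residual-class role above.

Replicate noise is log-normal and mean-preserving: a coefficient of
variation cv (default 0.1, typical silver-stain replicate scatter) maps to
a log-scale sd of sqrt(ln(1 + cv²)). Detection dropout is independent per
spot and gel (default 0.05), feeding the reproducibility filter. The
protein/spectrum simulator draws uniform-composition sequences over the 20
standard residues, and spectra keep each unique theoretical tryptic mass
with probability 0.7, perturb it by Gaussian relative error (sd 5 ppm),
and add 10 uniform contaminant peaks over the matchable window.

What the generator does **not** emulate: correlated spot intensities
(co-migrating proteins, isoform ladders), gel warping or saturation,
stage- or genotype-specific global intensity shifts, non-uniform amino
acid composition, and peak-intensity structure in spectra (intensities are
i.i.d. log-normal and unused by the search). Passing recovery tests
therefore demonstrates the statistical machinery under idealized
replicate noise, not performance on real gels.

## Measured behavior and problem sizes

At the default study conditions (10,000 spots, f = 3, cv = 0.1,
triplicates, no dropout) the pipeline recovers each plantable mode in
≥ 92% of spots; recovery falls with cv and rises with f across realistic
folds (checked at f ∈ {1.5, 2.25, 3} and cv ∈ {0.05, 0.2, 0.6}). PMF
identification accepts true-protein spectra in ≥ 95% of 200 seeded trials
and ranks the source protein first against a 500-protein database in
essentially all trials. These sizes (10,000 spots; 200 spectra × 1000
decoys) keep the full validation suite to a few minutes on one CPU while
leaving Monte-Carlo error well below the asserted margins.

## Known limitations

- %Vol normalization assumes comparable total signal per gel. When a large
  fraction of spots is planted with strong one-sided hybrid effects, the
  hybrid gels' totals inflate and normalization biases every spot's ratio;
  at extreme effect folds (f ≳ 6) this measurably erodes recovery of the
  dominance modes. Real experiments face the same trade-off, which is one
  reason the reference composition keeps differential spots rare.
- The empirical decoy threshold makes the significance call stochastic;
  with 1000 decoys the 95% quantile carries Monte-Carlo noise of a few
  percent of its value.
- The `D` mode and, at default settings, `+/-` are recovered imperfectly
  by construction (residual class; quantile placement near the additive
  boundary).
- Trait t-tests accept mean ± dispersion summaries; the dispersion is
  treated as a standard deviation by default with an explicit
  standard-error switch, and for the packaged grain-weight table both
  readings give the same verdicts.
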