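# Methods

## The model

A ratio biomarker over the five amyloid-β peptides (Aβ37, Aβ38, Aβ40,
Aβ42, Aβ43) assigns each peptide to the numerator, the denominator or
neither, with a non-negative weight:

    wCVR(x) = Σ_{i∈X1} k_i x_i / Σ_{j∈X2} k_j x_j,   X1 ∩ X2 = ∅, X1, X2 ≠ ∅.

Scores are invariant to rescaling either side's weights, so specs are
reported side-normalized (each side summing to 100%, denominator printed
negative). The classical ratios are special cases: Aβ42/40, Aβ40/42,
Aβ37/42, and short/long = Aβ(37+38+40)/(42+43) with unit weights on
reference-rescaled data, which is equivalent to natural-abundance weights
on control-relative data. Exhaustive enumeration of unit-weight ratios
over disjoint non-empty subsets yields 3^n − 2·2^n + 1 specs (180 for
n = 5).

Three objectives drive the weight search: `R` — squared Pearson
correlation between the score and age at onset (AAO) over mutation
carriers; `P` — area under the precision–recall curve with the minority
*control* class as positive (precision TN/(TN+FN) vs recall TN/(TN+FP)),
the right classification metric when controls are a small fraction of the
panel; `RP` — the product. The abnormal direction of any biomarker is
resolved empirically as the sign of (case median − control median), so no
peptide biology is hard-coded into the evaluation.

## Harmonization

Pipeline order: zero-filter → replicate averaging → total-abundance
normalization → division by per-cohort control means → (for additive
biomarkers only) rescaling by reference control proportions.

* Rows with any zero measurement are dropped (zeros arise from detection
  limits and poison denominators); the count is recorded in provenance.
* Replicates are averaged arithmetically *before* any ratio is formed;
  averaging per-replicate ratios instead is deliberately not the default
  because only peptide-level averages feed consistently into the control
  means of the next step.
* Control means use the arithmetic mean of total-normalized control
  values; after the step every cohort's control mean is exactly 1 per
  peptide (asserted to 1e-9).
* The reference proportions default to the panel's simulated control
  profile (or the built-in synthetic reference); supplied proportions are
  used verbatim.

A caveat worth stating precisely: a per-cohort diagonal assay bias
cancels *exactly* through the two-step harmonization only when the
cohort's control rows share a single relative peptide profile (i.e.
controls differ only in total loading). In that regime — which is the
method's working assumption about control cells — every downstream ratio
score is exactly bias-invariant, and harmonized values are bias-invariant
up to a per-row positive scalar that cancels in all ratios. With
within-control profile noise the cancellation is approximate (sub-percent
score shifts at 10% measurement CV in our simulations). The same caveat
applies to the order of the total-normalization and control-scaling
steps: they commute at the ratio-score level under the proportional-
control assumption, not value-by-value. We follow the order above
(normalize first), which is the order that makes the control-mean-equals-1
invariant hold.

## The synthetic cohort generator

The generator emulates the structure of multi-assay PSEN1 cell-model
panels; it is the test bed for every downstream stage. Defaults (chosen
once as the package's study conditions):

| parameter | default | meaning |
|---|---|---|
| cohorts | 3 | distinct assays/sites; cohort 0 unbiased |
| controls / cases per cohort | 3 / 40 | heavy class imbalance, few control lines |
| replicates | 3 | technical replicates per line |
| control profile | (0.13, 0.15, 0.60, 0.10, 0.02) | Aβ40 dominant, Aβ43 rarest |
| effect profile | (0.70, 0.80, 0.85, 1.80, 2.50) | per-peptide multiplier at severity 1 |
| severity | U(0.5, 1.5) per case | applied as effect^severity; spreads AAO across mutations |
| assay bias | log-uniform [0.5, 2] per cohort×peptide | multiplicative, cancelled by harmonization |
| noise_cv | 0.10 | lognormal measurement CV per replicate |
| planted spec | short/long, unit weights | AAO = 20 + 8 × planted value + N(0, 3²) years |
| zero_rate | 0 | set >0 to exercise the zero filter |

Concentration noise is multiplicative lognormal because assay
concentrations are strictly positive and errors scale with signal. The
planted AAO is computed on the noise-free, bias-free biology vector, so
in the noise-free limit the pipeline must recover R² = 1 exactly — that
limit anchors the parameter-recovery tests. Codons are drawn
independently of everything else, giving an exact null for the
mutation-position association.

What the generator does **not** emulate: γ-secretase kinetics, ELISA
optical-density/standard-curve structure, per-mutation biology (severity
is a scalar), within-control profile heterogeneity beyond measurement
noise, and non-multiplicative batch effects. Passing tests therefore
demonstrate the machinery's correctness under the stated statistical
structure, not performance on any real cohort.

## Genetic-algorithm search

The genome is one signed real weight per peptide (sign = side, magnitude
= weight; zero = unused). A standard real-coded GA is used: population
100, 200 generations, tournament selection (size 3), blend crossover
(BLX-0.5, rate 0.9), Gaussian mutation (σ = 0.2, rate 0.2 per gene),
elitism 1, genomes clipped to [−1, 1], 3 random restarts. Genomes with an
empty side are repaired by flipping the largest-magnitude gene. The four
benchmark ratios are injected into every initial population, so the
returned objective can never fall below any benchmark's on training data
(elitism makes the best-so-far monotone). After the restarts a
deterministic Nelder–Mead refinement of the winning sign pattern's
log-magnitudes polishes the weights; this is what brings weight recovery
on noise-free planted data inside 2 percentage points. Ties between
equal-objective specs are effectively resolved by the polish toward the
attractor of the final pattern. All randomness flows from a single seed
through `numpy` SeedSequence spawning; identical seeds give identical
results.

The inner loop evaluates the control-class PR AUC with a vectorized
average-precision routine that is tested to equal the packaged
`pr_auc_controls` (sklearn) to 1e-12 including ties; the GA makes tens of
thousands of evaluations per run and the library call dominates runtime
otherwise. Test-suite and acceptance runs use scaled-down GA budgets
(population 40–80, 40–100 generations, 1–3 restarts), which solve the
5-peptide problem reliably in our simulations.

## Validation

* **Bootstrap CIs**: 2000 resamples, within-class (stratified) for
  classification metrics; the reported point estimate is the bootstrap
  median with percentile 2.5/97.5 CIs (a `point="plugin"` switch reports
  the plug-in estimate instead). Replicates on which a metric is
  undefined are redrawn up to 10 times, then skipped with a warning.
* **LOOCV**: every sample held out once. Regression fits ordinary least
  squares of AAO on the score over training carriers. Classification
  resolves the abnormal direction on the training fold and thresholds at
  the most extreme training-control score in that direction; a held-out
  sample is a case only if *strictly* beyond the threshold, so training
  specificity is 1 by construction. Searched biomarkers can be
  re-optimized inside every training fold (leakage-safe) by passing a
  `SearchConfig`; fixed specs are scored once. MAE aggregates over
  carriers; F1 uses case as the positive class (a control-class variant is
  a flag away).
* **Paired comparisons**: Wilcoxon signed-rank on per-carrier absolute
  errors (zero differences dropped; exact null for n ≤ 25 without ties,
  otherwise the continuity-corrected normal approximation) and empirical
  two-sided bootstrap p-values for F1 differences,
  p = min(1, 2·min(P(Δ≤0), P(Δ≥0))). Benjamini–Hochberg runs over all
  comparisons reported in one call (one family), flagging adjusted
  p < 0.05.
* **Associations**: Pearson correlations carry Fisher-z 95% CIs; Kendall
  is tau-b (tie-corrected). Harmonized values exactly equal to 1 count as
  neither below nor above the control mean. Permutation importance
  permutes one peptide column at a time (100 permutations by default) and
  reports baseline-minus-permuted per metric; zero-weight peptides are
  exactly 0 by construction.

## Numerical conventions and degenerate inputs

Constant scores or AAO give R² = 0 with a warning rather than an error.
A cohort without controls, a panel without both classes, or a constant
codon vector raise typed errors naming the offender. Metric functions are
exact to floating point against brute-force oracles (pairwise win
fraction for ROC AUC; exhaustive threshold sweep for PR AUC) on random
instances including ties. The weight grid search defaults to the
one-at-a-time sweep (`mode="single"`); the joint sweep is available but
at step 0.02 over three free peptides costs ~10^6 metric evaluations, so
a coarser step is advisable there.

## Calibration of the mutation-position null test

The null-calibration check (codon independent of AAO by construction)
uses panels of 100 carriers: the asymptotic tau-b p-value is visibly
discrete and mildly conservative below roughly 50 observations, which a
Kolmogorov–Smirnov uniformity test over hundreds of replicates can
detect; at n ≈ 100 and beyond the approximation is clean. Real pooled
analyses of this kind involve ~200+ carriers.

## Known limitations

Harmonization ignores the spread (variance) of control measurements and
may amplify noise in low-abundance peptides such as Aβ43 — mitigated here
because searched composites learn weights rather than adding peptides
blindly. The GA's hyperparameters are reasonable defaults, not tuned
optima. No imputation is attempted for zero measurements. The package
evaluates biomarkers; it does not model mutation biology or predict AAO
from family history.
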