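# wcvr — weighted composite value ratios for Aβ peptide panels

Familial Alzheimer's disease (fAD) mutations in *PSEN1* shift γ-secretase
processing of APP away from short amyloid-β peptides (Aβ37, Aβ38, Aβ40)
toward the aggregation-prone long species (Aβ42, Aβ43). Ratios of these
peptides — Aβ42/40, Aβ37/42, the short/long ratio
Aβ(37+38+40)/(42+43) — are widely used biomarkers, both to separate
mutation carriers from controls and to predict the carrier's age at onset
(AAO). This package generalizes those fixed ratios to a **weighted
composite value ratio**

```
wCVR = Σ_{i∈X1} k_i·x_i / Σ_{j∈X2} k_j·x_j
```

where `X1` and `X2` are disjoint non-empty peptide sets and the
non-negative weights `k` are found by a genetic algorithm maximizing one
of three objectives: Pearson R² against AAO over mutation carriers
(`-R`), precision–recall AUC of the minority control class (`-P`), or
their product (`-RP`).

Because peptide panels come from different assays and sites, the package
first harmonizes cohorts onto a dimensionless control-relative scale:
drop samples with any zero measurement, average technical replicates,
normalize each sample to its five-peptide total, and divide each peptide
by its per-cohort control mean (control means become exactly 1). For
biomarkers that *add* peptides, values are rescaled by natural control
abundances so that summed peptides keep their orders-of-magnitude
differences.

The package ships a synthetic multi-cohort generator with the statistical
structure this analysis assumes (unequal control abundances, per-cohort
assay biases, directional fAD effect, heavy class imbalance, replicates,
AAO linear in a planted ratio), so the entire pipeline is testable without
access to patient-derived data. Intended users are biomarker
methodologists and computational biologists working with multi-assay
peptide panels.

## Worked example

```python
import wcvr

# 3 cohorts x (3 controls + 40 cases) x 3 replicates, assay biases drawn
# per cohort, AAO noisily linear in the planted short/long ratio
panel = wcvr.generate_cohorts(wcvr.SimulationConfig(seed=1))
harmonized = wcvr.harmonize(panel)

results = wcvr.run_configurations(
    harmonized, wcvr.SearchConfig(population_size=60, generations=80,
                                  n_restarts=2, seed=1))
spec = results["wCVR-R"].best_spec
print({p: round(w, 1) for p, w in spec.signed_weights().items()})
print(round(results["wCVR-R"].best_objective, 3))
```

prints

```
{'Ab37': 90.6, 'Ab38': -6.9, 'Ab40': 9.4, 'Ab42': -16.8, 'Ab43': -76.3}
0.765
```

Weights are signed normalized percentages: positive means numerator,
negative means denominator, each side summing to ±100. Here the search
put Aβ37 and Aβ40 in the numerator and the long species Aβ42/Aβ43 in the
denominator (Aβ38 enters marginally), and the composite explains 76.5% of
AAO variance on this panel — more than any fixed benchmark ratio
(`short/long` reaches R² = 0.735 on the same data). `wcvr.evaluate_biomarkers` adds ROC AUC,
control-class PR AUC and R² with stratified 2000-replicate bootstrap CIs;
`wcvr.loocv_evaluate` runs leave-one-out cross-validation with a
specificity-first threshold rule, and `wcvr.paired_comparisons` tests
biomarker differences (paired Wilcoxon on absolute errors, bootstrap
F1 differences, Benjamini–Hochberg at 5% FDR).

A command-line interface mirrors the library:

```bash
wcvr simulate --seed 1 --out panel.csv
wcvr harmonize panel.csv --out harmonized.csv
wcvr search panel.csv --objective RP --seed 1 --out spec.json
wcvr report --seed 1 --out-dir results/
```

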