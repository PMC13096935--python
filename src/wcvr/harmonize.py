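"""Cross-assay harmonization of multi-cohort peptide panels.

Different sites measure the same peptides with different assays, so raw
concentrations are not comparable across cohorts. The pipeline is:

1. ``filter_zero_samples`` — drop any measurement row containing a zero
   (zeros come from detection limits or assay failure and break ratios).
2. ``average_replicates`` — arithmetic mean of each peptide over a sample's
   technical replicates/batches, one row per line or genotype.
3. ``normalize_to_total`` — divide each row by its five-peptide sum,
   removing differences in total sample loading.
4. ``scale_by_control_means`` — divide each peptide by the mean of that
   peptide over the cohort's control samples, cancelling assay-specific
   multiplicative biases; afterwards every cohort's control mean is 1.
5. ``rescale_to_reference`` (only for biomarkers that ADD peptides) —
   multiply each peptide by its natural control abundance so that summed
   peptides keep their orders-of-magnitude differences.

Any per-cohort positive diagonal assay bias cancels exactly through steps
3-4, which is what makes cohorts combinable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .panel import HarmonizedPanel, PeptidePanel
from .peptides import PEPTIDES
from .simulate import DEFAULT_CONTROL_PROFILE

logger = logging.getLogger(__name__)


class HarmonizationError(ValueError):
    pass


@dataclass(frozen=True)
class ReferenceProportions:
    """Natural control relative abundances used to restore scale before
    additive biomarkers; fractions over the five peptides summing to 1."""

    proportions: Mapping[str, float]
    source: str = "synthetic-reference"

    def __post_init__(self) -> None:
        missing = [p for p in PEPTIDES if p not in self.proportions]
        if missing:
            raise HarmonizationError(f"reference proportions missing {missing}")
        vals = np.array([float(self.proportions[p]) for p in PEPTIDES])
        if (vals <= 0).any():
            raise HarmonizationError("reference proportions must be positive")
        if abs(vals.sum() - 1.0) > 1e-12:
            raise HarmonizationError(
                f"reference proportions must sum to 1 (got {vals.sum()!r})"
            )

    def vector(self) -> np.ndarray:
        return np.array([float(self.proportions[p]) for p in PEPTIDES])

    @classmethod
    def default(cls) -> "ReferenceProportions":
        return cls(dict(zip(PEPTIDES, DEFAULT_CONTROL_PROFILE)))

    @classmethod
    def from_controls(cls, panel: PeptidePanel, source: str = "panel-controls"
                      ) -> "ReferenceProportions":
        """Mean total-normalized control profile of a panel."""
        ctrl = panel.values[~panel.is_case]
        if len(ctrl) == 0:
            raise HarmonizationError("panel contains no controls")
        rel = ctrl / ctrl.sum(axis=1, keepdims=True)
        prof = rel.mean(axis=0)
        prof = prof / prof.sum()
        return cls(dict(zip(PEPTIDES, prof)), source=source)


def filter_zero_samples(panel: PeptidePanel) -> tuple[PeptidePanel, int]:
    """Remove every row with at least one zero measurement.

    Returns the filtered panel and the number of rows removed. An empty
    result is allowed but warned about.
    """
    has_zero = (panel.values == 0).any(axis=1)
    removed = int(has_zero.sum())
    if removed:
        per_cohort = panel.data.loc[has_zero, "cohort"].value_counts().to_dict()
        logger.info("zero filter removed %d rows: %s", removed, per_cohort)
    out = panel.data[~has_zero]
    if out.empty:
        warnings.warn("zero filter removed every row", stacklevel=2)
    return PeptidePanel(out), removed


def average_replicates(panel: PeptidePanel) -> PeptidePanel:
    """Average peptide values over replicates: one row per (cohort, sample).

    Group/mutation/codon/AAO annotations must be constant within a sample.
    """
    keys = ["cohort", "sample_id"]
    meta_cols = ["group", "mutation", "codon", "aao_years"]
    for col in ("group", "aao_years"):
        n_distinct = panel.data.groupby(keys, dropna=False)[col].nunique(dropna=False)
        if (n_distinct > 1).any():
            bad = n_distinct[n_distinct > 1].index.tolist()
            raise HarmonizationError(
                f"conflicting {col} annotations within sample(s) {bad}"
            )
    agg = {p: "mean" for p in PEPTIDES} | {c: "first" for c in meta_cols}
    out = panel.data.groupby(keys, as_index=False, dropna=False, sort=False).agg(agg)
    out["replicate"] = "mean"
    return PeptidePanel(out)


def normalize_to_total(panel: PeptidePanel) -> PeptidePanel:
    """Divide each row by its five-peptide total (relative concentrations)."""
    values = panel.values
    totals = values.sum(axis=1, keepdims=True)
    assert (totals > 0).all(), "zero totals must have been removed by the zero filter"
    return panel.with_values(values / totals)


def scale_by_control_means(panel: PeptidePanel) -> HarmonizedPanel:
    """Divide each peptide by its per-cohort control mean.

    After this step the control mean of every peptide in every cohort is 1,
    so values are dimensionless and comparable across assays.
    """
    control_means: dict[str, dict[str, float]] = {}
    values = panel.values.copy()
    for cohort, idx in panel.data.groupby("cohort", sort=False).groups.items():
        idx = np.asarray(idx)
        ctrl_idx = idx[~panel.is_case[idx]]
        if len(ctrl_idx) == 0:
            raise HarmonizationError(
                f"cohort {cohort!r} has no control samples; cannot harmonize"
            )
        means = values[ctrl_idx].mean(axis=0)
        control_means[str(cohort)] = dict(zip(PEPTIDES, means))
        values[idx] = values[idx] / means
    return HarmonizedPanel(
        panel.data.assign(**dict(zip(PEPTIDES, values.T))),
        control_means=control_means,
    )


def rescale_to_reference(
    panel: HarmonizedPanel, ref: ReferenceProportions | None = None
) -> HarmonizedPanel:
    """Multiply each peptide by its reference control proportion.

    Required before any biomarker that sums peptides (short/long, the
    enumerated combinations, wCVR): peptide abundances differ by orders of
    magnitude, and unit-weight sums on the control-relative scale would
    weight Ab43 as heavily as Ab40. Single-peptide ratios are unaffected up
    to a constant factor.
    """
    ref = ref or ReferenceProportions.default()
    out = panel.with_values(panel.values * ref.vector())
    out.reference_proportions = dict(ref.proportions)
    out.provenance["reference_source"] = ref.source
    return out


def harmonize(
    panel: PeptidePanel,
    ref: ReferenceProportions | None = None,
    rescale: bool = True,
) -> HarmonizedPanel:
    """Full pipeline: filter -> average -> total-normalize -> control-scale
    -> (optionally) reference-rescale."""
    filtered, removed = filter_zero_samples(panel)
    averaged = average_replicates(filtered)
    normalized = normalize_to_total(averaged)
    harmonized = scale_by_control_means(normalized)
    harmonized.n_zero_filtered = removed
    if rescale:
        harmonized = rescale_to_reference(harmonized, ref)
        harmonized.n_zero_filtered = removed
    return harmonized
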