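"""Evaluation metrics and stratified bootstrap confidence intervals.

Classification metrics follow the conventions of heavily imbalanced
case-control panels with few controls: alongside ROC AUC we report the
precision-recall AUC of the minority CONTROL class (precision TN/(TN+FN),
recall TN/(TN+FP)), whose uninformative baseline is the control prevalence
rather than 0.5. Regression quality against age-at-onset is the squared
Pearson correlation. Uncertainty is quantified with a 2000-replicate
bootstrap (stratified by class for classification metrics); the point
estimate reported is the bootstrap median with percentile 2.5/97.5 CIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score


class MetricError(ValueError):
    pass


@dataclass
class MetricEstimate:
    """A named metric with its bootstrap 95% CI."""

    name: str
    point: float
    ci_lower: float
    ci_upper: float
    n_bootstrap: int = 2000
    stratified: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_lower <= self.point <= self.ci_upper):
            raise MetricError(
                f"{self.name}: CI ({self.ci_lower}, {self.ci_upper}) does not "
                f"bracket point {self.point}"
            )

    def __str__(self) -> str:
        return f"{self.point:.3f}({self.ci_lower:.3f}, {self.ci_upper:.3f})"


def _check_scores(scores, is_case) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    is_case = np.asarray(is_case, dtype=bool)
    if scores.shape != is_case.shape:
        raise MetricError("scores and labels must have equal length")
    return scores, is_case


def roc_auc(scores: Sequence[float], is_case: Sequence[bool]) -> float:
    """ROC AUC with the higher-is-abnormal convention.

    Equals the Mann-Whitney pairwise win fraction (ties count 1/2) between
    case and control scores.
    """
    scores, is_case = _check_scores(scores, is_case)
    if not is_case.any() or is_case.all():
        raise MetricError("roc_auc needs both cases and controls")
    return float(roc_auc_score(is_case, scores))


def pr_auc_controls(scores: Sequence[float], is_case: Sequence[bool]) -> float:
    """Precision-recall AUC with CONTROL as the positive class.

    ``scores`` use the higher-is-abnormal convention, so controls are ranked
    by ``-scores``. Step-wise (average-precision) integration is used; linear
    interpolation of PR curves is optimistic.
    """
    scores, is_case = _check_scores(scores, is_case)
    if is_case.all():
        raise MetricError("pr_auc_controls needs at least one control")
    if not is_case.any():
        raise MetricError("pr_auc_controls needs at least one case")
    return float(average_precision_score(~is_case, -scores))


def pearson_r2_vs_aao(scores: Sequence[float], aao: Sequence[float]) -> float:
    """Squared Pearson correlation between biomarker score and age-at-onset.

    Computed over mutation carriers only (callers pass carrier rows). Zero
    variance in either variable yields 0 with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    aao = np.asarray(aao, dtype=float)
    if len(scores) < 3:
        raise MetricError("pearson_r2_vs_aao needs at least 3 carriers with AAO")
    if np.std(scores) == 0 or np.std(aao) == 0:
        warnings.warn("constant scores or AAO: R^2 defined as 0", stacklevel=2)
        return 0.0
    r = stats.pearsonr(scores, aao).statistic
    return float(r * r)


def bootstrap_ci(
    metric_fn: Callable[[np.ndarray], float],
    n_samples: int,
    *,
    strata: Sequence | None = None,
    n_boot: int = 2000,
    seed: int | None = None,
    name: str = "metric",
    point: str = "median",
    max_redraws: int = 10,
) -> MetricEstimate:
    """Percentile bootstrap CI for ``metric_fn`` over resampled row indices.

    ``metric_fn`` receives an integer index array into the original data and
    returns the metric on that resample. With ``strata`` given, resampling is
    with replacement within each stratum, preserving class counts in every
    replicate. A replicate on which the metric raises or returns NaN is
    redrawn up to ``max_redraws`` times, then skipped.

    ``point``: ``"median"`` reports the bootstrap median as the point
    estimate; ``"plugin"`` reports the metric on the original data.
    """
    rng = np.random.default_rng(seed)
    if strata is not None:
        strata = np.asarray(strata)
        groups = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    else:
        groups = [np.arange(n_samples)]

    def draw() -> np.ndarray:
        return np.concatenate([rng.choice(g, size=len(g), replace=True)
                               for g in groups])

    values = []
    n_skipped = 0
    for _ in range(n_boot):
        est = np.nan
        for _attempt in range(max_redraws):
            idx = draw()
            try:
                est = metric_fn(idx)
            except Exception:
                est = np.nan
            if np.isfinite(est):
                break
        if np.isfinite(est):
            values.append(est)
        else:
            n_skipped += 1
    if n_skipped:
        warnings.warn(
            f"{name}: {n_skipped} bootstrap replicates undefined after "
            f"{max_redraws} redraws each; skipped", stacklevel=2,
        )
    if not values:
        raise MetricError(f"{name}: metric undefined on every bootstrap replicate")
    values = np.asarray(values)
    lo, med, hi = np.percentile(values, [2.5, 50.0, 97.5])
    if point == "plugin":
        pt = float(metric_fn(np.arange(n_samples)))
        pt = min(max(pt, lo), hi)
    else:
        pt = float(med)
    return MetricEstimate(
        name=name, point=pt, ci_lower=float(lo), ci_upper=float(hi),
        n_bootstrap=n_boot, stratified=strata is not None,
    )
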