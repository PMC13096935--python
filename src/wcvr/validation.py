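"""Leave-one-out cross-validation and paired model comparisons.

Each biomarker is evaluated by LOOCV over all samples (carriers and
controls):

* regression — ordinary least squares of age-at-onset on the biomarker
  score, fitted on the training-fold mutation carriers, predicts the
  held-out carrier; aggregated as mean absolute error (MAE, years);
* classification — the abnormal direction is resolved on the training fold
  and the decision threshold is set at the most extreme training-control
  score in that direction, prioritizing specificity for the small control
  group; a held-out sample is called a case only if it lies strictly beyond
  the threshold; aggregated as the F1-score with case as the positive class.

Searched (wCVR) biomarkers are re-optimized inside every training fold when
a ``SearchConfig`` is supplied, so the held-out sample never influences the
weights. Pairwise model comparisons use the paired Wilcoxon signed-rank test
on absolute errors and empirical two-sided bootstrap p-values on F1
differences, with Benjamini-Hochberg control at 5% FDR over all comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import f1_score
from statsmodels.stats.multitest import multipletests

from .panel import HarmonizedPanel
from .ratios import RatioSpec, compute_ratio
from .search import SearchConfig, ga_search


class ValidationError(ValueError):
    pass


@dataclass
class LoocvReport:
    """Held-out predictions plus aggregate MAE and F1 for one biomarker."""

    name: str
    predictions: pd.DataFrame  # sample_id, group, aao, score, pred_aao, abs_err, pred_case
    mae: float
    f1: float
    n_train_control_errors: int = 0  # across all folds; 0 by construction
    fold_specs: list[RatioSpec] = field(default_factory=list)


def _classify(scores_train, is_case_train, score_test) -> tuple[bool, int]:
    """Threshold rule on one fold; returns (held-out call, # training
    controls misclassified by the fold's own rule)."""
    ctrl = scores_train[~is_case_train]
    case_med = np.median(scores_train[is_case_train])
    ctrl_med = np.median(ctrl)
    if case_med >= ctrl_med:
        thr = ctrl.max()
        call = bool(score_test > thr)
        train_errors = int((ctrl > thr).sum())
    else:
        thr = ctrl.min()
        call = bool(score_test < thr)
        train_errors = int((ctrl < thr).sum())
    return call, train_errors


def loocv_evaluate(
    specs: Mapping[str, RatioSpec | SearchConfig],
    data: HarmonizedPanel,
) -> dict[str, LoocvReport]:
    """LOOCV over all rows for each biomarker in ``specs``.

    Values may be fixed :class:`RatioSpec` objects or :class:`SearchConfig`
    objects; the latter re-run the GA on every training fold (leakage-safe).
    """
    n = len(data.data)
    is_case = data.is_case
    aao = data.aao
    if (~is_case).sum() < 2 or is_case.sum() < 2:
        raise ValidationError("LOOCV needs at least 2 controls and 2 cases")
    carriers = is_case & np.isfinite(aao)

    reports: dict[str, LoocvReport] = {}
    for name, spec_or_cfg in specs.items():
        fixed_scores = None
        if isinstance(spec_or_cfg, RatioSpec):
            fixed_scores = compute_ratio(spec_or_cfg, data).scores
        pred_aao = np.full(n, np.nan)
        pred_case = np.zeros(n, dtype=bool)
        used_scores = np.full(n, np.nan)
        train_errors = 0
        fold_specs: list[RatioSpec] = []
        for i in range(n):
            train = np.ones(n, dtype=bool)
            train[i] = False
            if (~is_case[train]).sum() == 0:
                warnings.warn(f"fold {i}: no training controls; skipped",
                              stacklevel=2)
                continue
            if fixed_scores is not None:
                scores = fixed_scores
            else:
                fold_panel = HarmonizedPanel(
                    data.data[train],
                    control_means=data.control_means,
                    reference_proportions=data.reference_proportions,
                )
                cfg = replace(spec_or_cfg, seed=spec_or_cfg.seed + i)
                result = ga_search(fold_panel, cfg)
                fold_specs.append(result.best_spec)
                scores = compute_ratio(result.best_spec, data).scores
            used_scores[i] = scores[i]
            # regression on training carriers
            tc = train & carriers
            if carriers[i]:
                if tc.sum() >= 2 and np.std(scores[tc]) > 0:
                    slope, intercept = np.polyfit(scores[tc], aao[tc], deg=1)
                    pred_aao[i] = slope * scores[i] + intercept
                else:
                    pred_aao[i] = float(np.mean(aao[tc])) if tc.sum() else np.nan
            call, errs = _classify(scores[train], is_case[train], scores[i])
            pred_case[i] = call
            train_errors += errs

        abs_err = np.abs(pred_aao - aao)
        mae = float(np.nanmean(abs_err[carriers]))
        f1 = float(f1_score(is_case, pred_case, zero_division=0.0))
        reports[name] = LoocvReport(
            name=name,
            predictions=pd.DataFrame(
                {
                    "sample_id": data.data["sample_id"],
                    "group": data.data["group"],
                    "aao": aao,
                    "score": used_scores,
                    "pred_aao": pred_aao,
                    "abs_err": abs_err,
                    "pred_case": pred_case,
                }
            ),
            mae=mae,
            f1=f1,
            n_train_control_errors=train_errors,
            fold_specs=fold_specs,
        )
    return reports


def _wilcoxon_p(x: np.ndarray, y: np.ndarray) -> float:
    """Paired two-sided Wilcoxon signed-rank p; zero differences dropped,
    exact null for n <= 25 (falling back to the continuity-corrected normal
    approximation with ties or larger n)."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[np.isfinite(d)]
    d = d[d != 0]
    if len(d) == 0:
        return 1.0
    if len(d) <= 25:
        try:
            return float(stats.wilcoxon(d, zero_method="wilcox", method="exact",
                                        alternative="two-sided").pvalue)
        except ValueError:
            pass
    return float(stats.wilcoxon(d, zero_method="wilcox", method="approx",
                                correction=True, alternative="two-sided").pvalue)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def paired_comparisons(
    reports: Mapping[str, LoocvReport],
    n_boot: int = 2000,
    fdr: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """All pairwise biomarker comparisons on shared LOOCV holdouts.

    Returns a tidy frame with one row per (pair, quantity): quantity 'mae'
    uses the paired Wilcoxon signed-rank test on per-carrier absolute
    errors; quantity 'f1' uses a paired bootstrap of the F1 difference with
    empirical two-sided p = min(1, 2*min(P(diff<=0), P(diff>=0))). BH
    adjustment runs over all rows; adjusted p < ``fdr`` flags significance.
    """
    names = list(reports)
    if len(names) < 2:
        raise ValidationError("need at least two reports to compare")
    base = reports[names[0]].predictions["sample_id"]
    for name in names[1:]:
        if not base.equals(reports[name].predictions["sample_id"]):
            raise ValidationError("reports were not built on identical holdout sets")
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in combinations(names, 2):
        pa, pb = reports[a].predictions, reports[b].predictions
        carrier = pa["abs_err"].notna() & pb["abs_err"].notna()
        ea = pa.loc[carrier, "abs_err"].to_numpy()
        eb = pb.loc[carrier, "abs_err"].to_numpy()
        rows.append(
            {"a": a, "b": b, "quantity": "mae",
             "difference": float(np.mean(ea) - np.mean(eb)),
             "pvalue": _wilcoxon_p(ea, eb)}
        )
        true = (pa["group"] == "case").to_numpy()
        ca = pa["pred_case"].to_numpy()
        cb = pb["pred_case"].to_numpy()
        n = len(true)
        idx = rng.integers(0, n, size=(n_boot, n))

        def f1_boot(pred: np.ndarray) -> np.ndarray:
            # F1 = 2TP / (2TP + FP + FN), vectorized over replicates
            tp = (pred[idx] & true[idx]).sum(axis=1)
            fp = (pred[idx] & ~true[idx]).sum(axis=1)
            fn = (~pred[idx] & true[idx]).sum(axis=1)
            denom = 2 * tp + fp + fn
            return np.divide(2 * tp, denom, out=np.zeros(n_boot, dtype=float),
                             where=denom > 0)

        diffs = f1_boot(ca) - f1_boot(cb)
        p = 2 * min(float(np.mean(diffs <= 0)), float(np.mean(diffs >= 0)))
        rows.append(
            {"a": a, "b": b, "quantity": "f1",
             "difference": reports[a].f1 - reports[b].f1,
             "pvalue": min(1.0, p)}
        )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = bh_adjust(table["pvalue"].to_numpy())
    table["significant"] = table["p_adjusted"] < fdr
    return table
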