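"""Per-peptide association analyses and weight-stability studies.

Covers: per-peptide correlations with age-at-onset (Pearson with Fisher-z
CIs plus Kendall tau-b), the fraction of case samples deviating above/below
the control mean per peptide, mutation-position association tests, the
bootstrap distribution of searched wCVR weights, a weight grid search
around fixed baseline ratios, and permutation feature importance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import average_replicates, filter_zero_samples, normalize_to_total
from .metrics import pearson_r2_vs_aao, pr_auc_controls, roc_auc
from .panel import HarmonizedPanel, PeptidePanel
from .peptides import PEPTIDES
from .ratios import RatioSpec, compute_ratio
from .search import SearchConfig, ga_search

logger = logging.getLogger(__name__)


class AssociationError(ValueError):
    pass


def fisher_z_ci(r: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Fisher z-transform CI for a Pearson correlation; clamps at +/-1."""
    if n < 4:
        return (-1.0, 1.0)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return (r, r)
    z = np.arctanh(r)
    half = stats.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def peptide_aao_correlations(
    panel: PeptidePanel, harmonized: HarmonizedPanel | None = None
) -> pd.DataFrame:
    """Per-cohort and pooled peptide-vs-AAO correlations.

    Per-cohort rows use total-normalized (relative-to-sum) values before
    cross-assay harmonization; the pooled 'all' rows use the harmonized
    values (harmonization is what makes cohorts poolable). Cohorts with
    fewer than 3 carriers are skipped. Reports Pearson rho with two-sided p
    and Fisher-z 95% CI, and Kendall tau-b with two-sided p.
    """
    filtered, _ = filter_zero_samples(panel)
    relative = normalize_to_total(average_replicates(filtered))
    if harmonized is None:
        from .harmonize import scale_by_control_means

        harmonized = scale_by_control_means(relative)

    def rows_for(frame: pd.DataFrame, label: str) -> list[dict]:
        carriers = frame[(frame["group"] == "case") & frame["aao_years"].notna()]
        out = []
        if len(carriers) < 3:
            logger.info("scope %s: <3 carriers with AAO; skipped", label)
            return out
        aao = carriers["aao_years"].to_numpy(dtype=float)
        for p in PEPTIDES:
            x = carriers[p].to_numpy(dtype=float)
            pear = stats.pearsonr(x, aao)
            lo, hi = fisher_z_ci(pear.statistic, len(x))
            ken = stats.kendalltau(x, aao)
            out.append(
                {"scope": label, "peptide": p,
                 "pearson_rho": float(pear.statistic),
                 "pearson_p": float(pear.pvalue),
                 "ci_lower": lo, "ci_upper": hi,
                 "kendall_tau": float(ken.statistic),
                 "kendall_p": float(ken.pvalue)}
            )
        return out

    rows: list[dict] = []
    for cohort, sub in relative.data.groupby("cohort", sort=False):
        rows.extend(rows_for(sub, str(cohort)))
    rows.extend(rows_for(harmonized.data, "all"))
    return pd.DataFrame(rows)


def deviation_proportions(panel: HarmonizedPanel) -> pd.DataFrame:
    """Fractions of case samples deviating below/above the control mean (=1)
    per peptide. Values exactly equal to 1 count in neither strict fraction,
    so below + above + at == 1."""
    cases = panel.values[panel.is_case]
    if len(cases) == 0:
        raise AssociationError("panel contains no case samples")
    rows = []
    for j, p in enumerate(PEPTIDES):
        below = float(np.mean(cases[:, j] < 1.0))
        above = float(np.mean(cases[:, j] > 1.0))
        rows.append({"peptide": p, "below": below, "above": above,
                     "at": 1.0 - below - above})
    return pd.DataFrame(rows)


@dataclass
class PositionAssociation:
    """Mutation-codon association statistics for one outcome."""

    outcome: str
    n: int
    kendall_tau: float
    kendall_z: float
    kendall_p: float
    pearson_r: float
    pearson_t: float
    df: int
    pearson_p: float


def _assoc(codon: np.ndarray, y: np.ndarray, outcome: str) -> PositionAssociation:
    n = len(codon)
    if np.unique(codon).size < 2 or np.unique(y).size < 2:
        raise AssociationError(f"{outcome}: degenerate (constant) inputs")
    ken = stats.kendalltau(codon, y)
    z = float(np.sign(ken.statistic) * stats.norm.isf(ken.pvalue / 2)) \
        if ken.pvalue > 0 else np.inf
    pear = stats.pearsonr(codon, y)
    r = float(pear.statistic)
    df = n - 2
    t = r * np.sqrt(df / (1 - r * r)) if abs(r) < 1 else np.inf
    return PositionAssociation(
        outcome=outcome, n=n,
        kendall_tau=float(ken.statistic), kendall_z=z,
        kendall_p=float(ken.pvalue),
        pearson_r=r, pearson_t=float(t), df=df,
        pearson_p=float(pear.pvalue),
    )


def mutation_position_association(panel: HarmonizedPanel) -> dict[str, PositionAssociation]:
    """Association of mutation codon with age-at-onset and with the Ab42/40
    ratio, over carriers with a recorded codon."""
    d = panel.data
    mask = (d["group"] == "case") & d["codon"].notna() & d["aao_years"].notna()
    if mask.sum() < mask[(d["group"] == "case")].sum():
        logger.info("excluded %d carriers without codon/AAO",
                    int((d["group"] == "case").sum() - mask.sum()))
    carriers = d[mask]
    if len(carriers) < 3:
        raise AssociationError("need at least 3 carriers with codon and AAO")
    codon = carriers["codon"].to_numpy(dtype=float)
    aao = carriers["aao_years"].to_numpy(dtype=float)
    spec = RatioSpec("Ab42/40", numerator={"Ab42": 1.0}, denominator={"Ab40": 1.0})
    sub = HarmonizedPanel(
        carriers, control_means=panel.control_means,
        reference_proportions=panel.reference_proportions,
    )
    ratio = np.asarray(spec.evaluate(sub.values), dtype=float)
    return {
        "aao": _assoc(codon, aao, "aao"),
        "ab42_40": _assoc(codon, ratio, "ab42_40"),
    }


@dataclass
class WeightDistribution:
    """Signed normalized wCVR weights across stratified bootstrap replicates."""

    weights: pd.DataFrame  # one row per replicate, one column per peptide
    n_replicates: int
    restarts: int

    def summary(self) -> pd.DataFrame:
        q = self.weights.quantile([0.25, 0.5, 0.75])
        q.index = ["q25", "median", "q75"]
        return q

    def sign_consistency(self) -> pd.Series:
        """Fraction of replicates in which each peptide keeps its modal side
        (counting only replicates where the peptide is active)."""
        out = {}
        for p in self.weights.columns:
            w = self.weights[p].to_numpy()
            active = w != 0
            if not active.any():
                out[p] = np.nan
                continue
            frac_neg = float(np.mean(w[active] < 0))
            out[p] = max(frac_neg, 1 - frac_neg)
        return pd.Series(out)


def bootstrap_weight_distribution(
    data: HarmonizedPanel,
    config: SearchConfig,
    n_boot: int = 200,
    restarts: int = 3,
    seed: int | None = None,
) -> WeightDistribution:
    """Stratified bootstrap of the GA search: per replicate, resample rows
    within class, run the search best-of-``restarts``, and record the signed
    normalized weights of the winning spec."""
    rng = np.random.default_rng(seed)
    is_case = data.is_case
    groups = [np.flatnonzero(is_case), np.flatnonzero(~is_case)]
    rows = []
    from dataclasses import replace

    for b in range(n_boot):
        idx = np.concatenate([rng.choice(g, size=len(g), replace=True)
                              for g in groups])
        boot = HarmonizedPanel(
            data.data.iloc[idx],
            control_means=data.control_means,
            reference_proportions=data.reference_proportions,
        )
        cfg = replace(config, n_restarts=restarts,
                      seed=int(rng.integers(0, 2**31 - 1)))
        try:
            result = ga_search(boot, cfg)
        except Exception as exc:  # degenerate resample
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
            continue
        rows.append(result.best_spec.signed_weights())
    return WeightDistribution(
        weights=pd.DataFrame(rows, columns=list(PEPTIDES)),
        n_replicates=len(rows), restarts=restarts,
    )


_GRID_BASELINES = {
    "R": ("Ab42/40", {"Ab40": "num", "Ab42": "den"}),
    "P": ("Ab37/42", {"Ab37": "num", "Ab42": "den"}),
}


def grid_search_weights(
    data: HarmonizedPanel,
    objective: str = "R",
    step: float = 0.02,
    mode: str = "single",
) -> pd.DataFrame:
    """Metric landscape around a fixed baseline ratio.

    The baseline (Ab42/40 for objective ``R``, Ab37/42 for ``P``) keeps unit
    weights on its established sides; every remaining peptide is swept over
    weights 0..1 by ``step`` on either side. ``mode="single"`` varies one
    peptide at a time (tidy output: peptide, side, weight, value);
    ``mode="joint"`` sweeps all free peptides jointly (columns per peptide:
    signed weight). The joint sweep at the default step is large (~1e6
    points); prefer a coarser step there.
    """
    if step <= 0:
        raise AssociationError("step must be positive")
    if objective not in _GRID_BASELINES:
        raise AssociationError("objective must be 'R' or 'P'")
    base_name, base_sides = _GRID_BASELINES[objective]
    free = [p for p in PEPTIDES if p not in base_sides]
    weights = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)

    def evaluate(num: dict, den: dict) -> float:
        spec = RatioSpec("grid", numerator=num, denominator=den)
        scores = compute_ratio(spec, data)
        if objective == "R":
            carriers = data.is_case & np.isfinite(data.aao)
            return pearson_r2_vs_aao(scores.scores[carriers], data.aao[carriers])
        return pr_auc_controls(scores.oriented(), data.is_case)

    base_num = {p: 1.0 for p, s in base_sides.items() if s == "num"}
    base_den = {p: 1.0 for p, s in base_sides.items() if s == "den"}

    rows = []
    if mode == "single":
        for p in free:
            for side in ("num", "den"):
                for w in weights:
                    num = dict(base_num)
                    den = dict(base_den)
                    if w > 0:
                        (num if side == "num" else den)[p] = float(w)
                    rows.append(
                        {"baseline": base_name, "peptide": p, "side": side,
                         "weight": float(w), "objective": objective,
                         "value": evaluate(num, den)}
                    )
    elif mode == "joint":
        signed = np.concatenate([-weights[weights > 0][::-1], weights])
        for combo in product(signed, repeat=len(free)):
            num = dict(base_num)
            den = dict(base_den)
            for p, w in zip(free, combo):
                if w > 0:
                    num[p] = float(w)
                elif w < 0:
                    den[p] = float(-w)
            row = {"baseline": base_name, "objective": objective,
                   "value": evaluate(num, den)}
            row.update({p: float(w) for p, w in zip(free, combo)})
            rows.append(row)
    else:
        raise AssociationError("mode must be 'single' or 'joint'")
    return pd.DataFrame(rows)


def permutation_importance(
    spec: RatioSpec,
    data: HarmonizedPanel,
    metrics: tuple[str, ...] = ("roc_auc", "pr_auc", "r2"),
    n_perm: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutation feature importance of each peptide under ``spec``.

    Importance = baseline metric minus the mean metric over ``n_perm``
    panels with that peptide's column permuted across samples. Peptides with
    zero weight in the spec have importance exactly 0 for every metric.
    """
    rng = np.random.default_rng(seed)
    signed = spec.signed_weights()
    carriers = data.is_case & np.isfinite(data.aao)

    def all_metrics(values: np.ndarray) -> dict[str, float]:
        scores = np.asarray(spec.evaluate(values), dtype=float)
        case_med = np.median(scores[data.is_case])
        ctrl_med = np.median(scores[~data.is_case])
        oriented = scores if case_med >= ctrl_med else -scores
        out = {}
        if "roc_auc" in metrics:
            out["roc_auc"] = roc_auc(oriented, data.is_case)
        if "pr_auc" in metrics:
            out["pr_auc"] = pr_auc_controls(oriented, data.is_case)
        if "r2" in metrics:
            out["r2"] = pearson_r2_vs_aao(scores[carriers], data.aao[carriers])
        return out

    baseline = all_metrics(data.values)
    rows = []
    for j, p in enumerate(PEPTIDES):
        if signed[p] == 0.0:
            rows.append({"peptide": p, **{m: 0.0 for m in baseline}})
            continue
        sums = {m: 0.0 for m in baseline}
        for _ in range(n_perm):
            perm_values = data.values.copy()
            perm_values[:, j] = perm_values[rng.permutation(len(perm_values)), j]
            for m, v in all_metrics(perm_values).items():
                sums[m] += v
        rows.append({"peptide": p,
                     **{m: baseline[m] - sums[m] / n_perm for m in baseline}})
    return pd.DataFrame(rows)
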