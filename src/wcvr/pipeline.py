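"""End-to-end pipeline: simulate/load -> harmonize -> evaluate -> report.

``run_pipeline`` orchestrates the full analysis and writes a deterministic
artifact set (harmonized panel, biomarker metric tables with bootstrap CIs,
searched wCVR weight tables, LOOCV report, correlation tables, and a JSON
manifest) into an output directory. Everything stochastic derives from the
single config seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .associations import (
    deviation_proportions,
    mutation_position_association,
    peptide_aao_correlations,
)
from .harmonize import ReferenceProportions, harmonize
from .io import load_panel, save_harmonization_provenance, save_panel
from .metrics import bootstrap_ci, pearson_r2_vs_aao, pr_auc_controls, roc_auc
from .panel import HarmonizedPanel, PeptidePanel
from .ratios import RatioSpec, benchmark_specs, compute_ratio, enumerate_ratio_specs
from .search import SearchConfig, run_configurations
from .simulate import SimulationConfig, generate_cohorts
from .validation import loocv_evaluate, paired_comparisons

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """What to run and where to write it."""

    input_path: str | None = None          # CSV panel; None -> simulate
    simulation: SimulationConfig | None = None
    output_dir: str = "wcvr_results"
    biomarkers: tuple[str, ...] = ("benchmarks", "wcvr")  # + "enumeration"
    n_bootstrap: int = 2000
    run_loocv: bool = True
    loocv_resample_wcvr: bool = False      # re-search wCVR inside every fold
    search: SearchConfig = field(default_factory=SearchConfig)
    seed: int = 0


def evaluate_biomarkers(
    specs: dict[str, RatioSpec],
    panel: HarmonizedPanel,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Metric table (ROC AUC, control and case PR AUC, R^2) with stratified
    bootstrap CIs, one row per biomarker."""
    is_case = panel.is_case
    carriers = is_case & np.isfinite(panel.aao)
    rows = []
    for i, (name, spec) in enumerate(specs.items()):
        scores = compute_ratio(spec, panel)
        oriented = scores.oriented()

        def auc_fn(idx, oriented=oriented):
            return roc_auc(oriented[idx], is_case[idx])

        def pr_ctrl_fn(idx, oriented=oriented):
            return pr_auc_controls(oriented[idx], is_case[idx])

        def pr_case_fn(idx, oriented=oriented):
            # PR AUC of the fAD (case) class: flip both labels and direction
            return pr_auc_controls(-oriented[idx], ~is_case[idx])

        carrier_scores = scores.scores[carriers]
        carrier_aao = panel.aao[carriers]

        def r2_fn(idx, s=carrier_scores, a=carrier_aao):
            return pearson_r2_vs_aao(s[idx], a[idx])

        row = {"biomarker": name, "orientation": scores.orientation}
        for metric, fn, stratified, n in (
            ("roc_auc", auc_fn, True, len(is_case)),
            ("pr_auc_controls", pr_ctrl_fn, True, len(is_case)),
            ("pr_auc_fad", pr_case_fn, True, len(is_case)),
            ("r2", r2_fn, False, int(carriers.sum())),
        ):
            strata = is_case if stratified else None
            est = bootstrap_ci(fn, n, strata=strata, n_boot=n_boot,
                               seed=seed + i, name=f"{name}:{metric}")
            row[metric] = est.point
            row[f"{metric}_ci"] = str(est)
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the manifest (also written to
    ``manifest.json`` in the output directory)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.input_path:
        panel = load_panel(config.input_path)
        ref = None  # default reference proportions
    else:
        sim = config.simulation or SimulationConfig(seed=config.seed)
        panel = generate_cohorts(sim)
        save_panel(panel, out / "panel.csv")
        (out / "simulation_config.json").write_text(sim.to_json())
        ref = ReferenceProportions(
            dict(zip(("Ab37", "Ab38", "Ab40", "Ab42", "Ab43"),
                     sim.control_abundance_profile)),
            source="simulation-control-profile",
        )

    harmonized = harmonize(panel, ref=ref, rescale=True)
    save_panel(harmonized, out / "harmonized.csv", fmt="wide")
    save_harmonization_provenance(harmonized, out / "harmonization.json")

    specs: dict[str, RatioSpec] = {}
    search_results = {}
    if "benchmarks" in config.biomarkers:
        specs.update({s.name: s for s in benchmark_specs()})
    if "enumeration" in config.biomarkers:
        specs.update({s.name: s for s in enumerate_ratio_specs()})
    if "wcvr" in config.biomarkers:
        search_cfg = dataclasses.replace(config.search, seed=config.seed)
        search_results = run_configurations(harmonized, search_cfg)
        for name, result in search_results.items():
            specs[name] = result.best_spec
        weights = pd.DataFrame(
            [{"biomarker": n, **r.best_spec.signed_weights(),
              "objective": r.objective, "objective_value": r.best_objective}
             for n, r in search_results.items()]
        )
        weights.to_csv(out / "wcvr_weights.tsv", sep="\t", index=False)
        for name, result in search_results.items():
            (out / f"{name}.json").write_text(
                json.dumps({**result.best_spec.to_dict(),
                            "objective": result.objective,
                            "objective_value": result.best_objective,
                            "traces": [t.tolist() for t in result.traces]},
                           indent=2))

    metrics_table = evaluate_biomarkers(specs, harmonized,
                                        n_boot=config.n_bootstrap,
                                        seed=config.seed)
    metrics_table.to_csv(out / "metrics.tsv", sep="\t", index=False)

    correlations = peptide_aao_correlations(panel, harmonized=None)
    correlations.to_csv(out / "correlations.tsv", sep="\t", index=False)
    deviations = deviation_proportions(harmonize(panel, rescale=False))
    deviations.to_csv(out / "deviation_proportions.tsv", sep="\t", index=False)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_rows": panel.n_rows,
        "n_zero_filtered": harmonized.n_zero_filtered,
        "biomarkers": sorted(specs),
        "outputs": sorted(p.name for p in out.iterdir()),
    }

    if config.run_loocv:
        bench_names = {s.name for s in benchmark_specs()}
        loocv_specs: dict = {n: s for n, s in specs.items()
                             if n in bench_names or n.startswith("wCVR")}
        if config.loocv_resample_wcvr:
            for name in search_results:
                loocv_specs[name] = dataclasses.replace(
                    config.search,
                    objective=search_results[name].objective,
                    seed=config.seed)
        reports = loocv_evaluate(loocv_specs, harmonized)
        summary = pd.DataFrame(
            [{"biomarker": n, "mae": r.mae, "f1": r.f1} for n, r in reports.items()]
        )
        summary.to_csv(out / "loocv_summary.tsv", sep="\t", index=False)
        if len(reports) >= 2:
            comparisons = paired_comparisons(reports, seed=config.seed)
            comparisons.to_csv(out / "loocv_comparisons.tsv", sep="\t", index=False)
        manifest["loocv"] = {n: {"mae": r.mae, "f1": r.f1}
                             for n, r in reports.items()}

    manifest["outputs"] = sorted(p.name for p in out.iterdir())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete: %s", out)
    return manifest
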