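"""Shared fixtures: small hand-built panels and simulated cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import wcvr
from wcvr.peptides import PEPTIDES


def make_panel(rows: list[dict]) -> wcvr.PeptidePanel:
    """Build a panel from dicts of the form
    {sample_id, cohort, group, values: 5-seq, aao?, replicate?}."""
    records = []
    for r in rows:
        records.append(
            {
                "sample_id": r["sample_id"],
                "cohort": r.get("cohort", "c0"),
                "replicate": r.get("replicate", "r0"),
                "group": r["group"],
                "mutation": r.get("mutation"),
                "codon": r.get("codon"),
                "aao_years": r.get("aao", np.nan),
                **dict(zip(PEPTIDES, r["values"])),
            }
        )
    return wcvr.PeptidePanel(pd.DataFrame(records))


@pytest.fixture(scope="session")
def default_panel() -> wcvr.PeptidePanel:
    return wcvr.generate_cohorts(wcvr.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_harmonized(default_panel) -> wcvr.HarmonizedPanel:
    return wcvr.harmonize(default_panel)


@pytest.fixture(scope="session")
def noise_free_planted() -> tuple[wcvr.SimulationConfig, wcvr.HarmonizedPanel]:
    """Large noise-free single-cohort panel whose AAO is an exact linear
    function of the planted short/long ratio."""
    cfg = wcvr.SimulationConfig(
        n_cohorts=1, n_controls=20, n_cases=200, n_replicates=1,
        noise_cv=0.0, aao_noise_sd=0.0, zero_rate=0.0, seed=7,
    )
    ref = wcvr.ReferenceProportions(
        dict(zip(PEPTIDES, cfg.control_abundance_profile)), source="sim")
    return cfg, wcvr.harmonize(wcvr.generate_cohorts(cfg), ref=ref)


# -- independent oracles ---------------------------------------------------

def roc_auc_oracle(scores, is_case) -> float:
    """Pairwise Mann-Whitney win fraction: wins + half-ties over all
    (case, control) pairs."""
    scores = np.asarray(scores, dtype=float)
    is_case = np.asarray(is_case, dtype=bool)
    case = scores[is_case]
    ctrl = scores[~is_case]
    wins = sum((c > k) + 0.5 * (c == k) for c in case for k in ctrl)
    return float(wins) / (len(case) * len(ctrl))


def pr_auc_controls_oracle(scores, is_case) -> float:
    """Exhaustive threshold sweep, control class positive, scores with the
    higher-is-abnormal convention (controls called at score <= t); step-wise
    summation over increasing recall."""
    scores = np.asarray(scores, dtype=float)
    is_case = np.asarray(is_case, dtype=bool)
    n_controls = int((~is_case).sum())
    auc = 0.0
    prev_recall = 0.0
    for t in np.sort(np.unique(scores)):
        called = scores <= t
        tn = int((called & ~is_case).sum())
        fn = int((called & is_case).sum())
        precision = tn / (tn + fn)
        recall = tn / n_controls
        auc += (recall - prev_recall) * precision
        prev_recall = recall
    return auc


def kendall_tau_b_oracle(x, y) -> float:
    """Tau-b from explicit concordant/discordant pair counts."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = np.sign(x[i] - x[j])
            dy = np.sign(y[i] - y[j])
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx == dy:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    # pair counts with ties in x / y (including joint ties)
    ties_x = n0 - (conc + disc + ty)
    ties_y = n0 - (conc + disc + tx)
    return (conc - disc) / np.sqrt((n0 - ties_x) * (n0 - ties_y))
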