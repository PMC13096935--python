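"""Readers and writers for peptide panels and result tables.

Panels travel as plain CSV in either long format (columns sample_id,
cohort, replicate, group, mutation, codon, aao_years, peptide, value) or
wide format (one column per peptide). Peptide labels are canonicalized at
the boundary; a column for an unsupported species such as Ab39 is an error
with an actionable message rather than a silent drop.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .panel import HarmonizedPanel, PanelValidationError, PeptidePanel
from .peptides import PEPTIDES, canonical_peptide

logger = logging.getLogger(__name__)

LONG_COLUMNS = ("sample_id", "cohort", "replicate", "group", "mutation",
                "codon", "aao_years", "peptide", "value")
_META = ("sample_id", "cohort", "replicate", "group", "mutation", "codon",
         "aao_years")


def _canonicalize_wide(df: pd.DataFrame) -> pd.DataFrame:
    rename = {}
    for col in df.columns:
        if col in _META or col in PEPTIDES:
            continue
        rename[col] = canonical_peptide(col)  # raises for Ab39 / unknown
    return df.rename(columns=rename)


def load_panel(path: str | Path) -> PeptidePanel:
    """Load a panel CSV (long or wide format) into a validated panel.

    Long format is detected by the presence of 'peptide' and 'value'
    columns and pivoted to wide; both encodings of the same data load to
    identical panels.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if {"peptide", "value"}.issubset(df.columns):
        df = df.copy()
        df["peptide"] = [canonical_peptide(p) for p in df["peptide"]]
        keys = [c for c in ("sample_id", "cohort", "replicate")
                if c in df.columns]
        values = df.pivot(index=keys, columns="peptide", values="value")
        meta = df.drop(columns=["peptide", "value"]).drop_duplicates(subset=keys)
        wide = meta.merge(values.reset_index(), on=keys)
        missing = wide[list(PEPTIDES)].isna().any(axis=1)
        if missing.any():
            raise PanelValidationError(
                f"{path}: {int(missing.sum())} sample(s) lack one or more of "
                f"the five peptides (rows {wide.index[missing].tolist()[:5]})"
            )
        df = wide
    else:
        df = _canonicalize_wide(df)
    try:
        panel = PeptidePanel(df)
    except PanelValidationError as exc:
        raise PanelValidationError(f"{path}: {exc}") from exc
    counts = panel.data.groupby(["cohort", "group"]).size()
    logger.info("loaded %d rows from %s\n%s", panel.n_rows, path, counts)
    return panel


def save_panel(panel: PeptidePanel | HarmonizedPanel, path: str | Path,
               fmt: str = "long") -> None:
    """Write a panel as CSV; ``fmt`` is ``"long"`` or ``"wide"``."""
    path = Path(path)
    df = panel.data
    if fmt == "wide":
        df.to_csv(path, index=False)
        return
    long = df.melt(id_vars=list(_META), value_vars=list(PEPTIDES),
                   var_name="peptide", value_name="value")
    long.to_csv(path, index=False)


def save_harmonization_provenance(panel: HarmonizedPanel, path: str | Path) -> None:
    """JSON sidecar: per-cohort control means, zero-filter count, reference."""
    payload = {
        "control_means": panel.control_means,
        "n_zero_filtered": panel.n_zero_filtered,
        "reference_proportions": panel.reference_proportions,
        **panel.provenance,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
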