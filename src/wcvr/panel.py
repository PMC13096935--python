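"""Tabular containers for per-sample peptide concentration panels.

``PeptidePanel`` wraps a wide pandas DataFrame with one row per measurement
(sample x replicate) and one column per peptide, plus the cohort/group/AAO
annotations the downstream analysis needs. ``HarmonizedPanel`` holds the
dimensionless control-relative values produced by the harmonization pipeline
together with provenance (per-cohort control means, zero-filter counts,
reference proportions applied).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .peptides import PEPTIDES

META_COLUMNS = (
    "sample_id",
    "cohort",
    "replicate",
    "group",
    "mutation",
    "codon",
    "aao_years",
)

GROUPS = ("control", "case")


class PanelValidationError(ValueError):
    """Raised when a panel violates the schema (missing peptides, negative
    concentrations, AAO on controls, unknown group labels)."""


def _validate_frame(data: pd.DataFrame, *, context: str) -> pd.DataFrame:
    missing = [c for c in ("sample_id", "cohort", "group") if c not in data.columns]
    if missing:
        raise PanelValidationError(f"{context}: missing required columns {missing}")
    missing_pep = [p for p in PEPTIDES if p not in data.columns]
    if missing_pep:
        raise PanelValidationError(f"{context}: missing peptide columns {missing_pep}")

    data = data.copy()
    for col in META_COLUMNS:
        if col not in data.columns:
            data[col] = np.nan
    data = data[list(META_COLUMNS) + list(PEPTIDES)]

    bad_group = ~data["group"].isin(GROUPS)
    if bad_group.any():
        rows = data.index[bad_group].tolist()[:5]
        raise PanelValidationError(
            f"{context}: group must be one of {GROUPS}; offending rows {rows}"
        )

    values = data[list(PEPTIDES)].to_numpy(dtype=float)
    if np.isnan(values).any():
        rows = data.index[np.isnan(values).any(axis=1)].tolist()[:5]
        raise PanelValidationError(
            f"{context}: all five peptides required for every row; "
            f"missing values at rows {rows}"
        )
    if (values < 0).any():
        rows = data.index[(values < 0).any(axis=1)].tolist()[:5]
        raise PanelValidationError(
            f"{context}: negative concentrations at rows {rows}; assays report "
            "non-negative values"
        )
    data[list(PEPTIDES)] = values

    is_control = data["group"] == "control"
    if data.loc[is_control, "aao_years"].notna().any():
        rows = data.index[is_control & data["aao_years"].notna()].tolist()[:5]
        raise PanelValidationError(
            f"{context}: controls must not carry an age-at-onset; rows {rows}"
        )
    return data.reset_index(drop=True)


@dataclass
class PeptidePanel:
    """Raw (or partially processed) per-sample peptide panel.

    ``data`` columns: sample_id, cohort, replicate, group, mutation, codon,
    aao_years, Ab37, Ab38, Ab40, Ab42, Ab43.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = _validate_frame(self.data, context="PeptidePanel")

    # -- convenience accessors -------------------------------------------
    @property
    def values(self) -> np.ndarray:
        """(n_rows, 5) float array of peptide values in PEPTIDES order."""
        return self.data[list(PEPTIDES)].to_numpy(dtype=float)

    @property
    def is_case(self) -> np.ndarray:
        return (self.data["group"] == "case").to_numpy()

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def cohorts(self) -> list[str]:
        return list(pd.unique(self.data["cohort"]))

    def with_values(self, values: np.ndarray) -> "PeptidePanel":
        out = self.data.copy()
        out[list(PEPTIDES)] = np.asarray(values, dtype=float)
        return PeptidePanel(out)


@dataclass
class HarmonizedPanel:
    """Dimensionless control-relative panel: one row per (cohort, sample).

    Invariant: within each cohort the mean of each peptide over control rows
    is 1 (before any reference-proportion rescaling).
    """

    data: pd.DataFrame
    control_means: dict[str, dict[str, float]] = field(default_factory=dict)
    reference_proportions: dict[str, float] | None = None
    n_zero_filtered: int = 0
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = _validate_frame(self.data, context="HarmonizedPanel")
        values = self.data[list(PEPTIDES)].to_numpy(dtype=float)
        if (values <= 0).any():
            raise PanelValidationError(
                "HarmonizedPanel values must be strictly positive"
            )

    @property
    def values(self) -> np.ndarray:
        return self.data[list(PEPTIDES)].to_numpy(dtype=float)

    @property
    def is_case(self) -> np.ndarray:
        return (self.data["group"] == "case").to_numpy()

    @property
    def aao(self) -> np.ndarray:
        return self.data["aao_years"].to_numpy(dtype=float)

    def carriers(self) -> pd.DataFrame:
        """Mutation carriers with a recorded age-at-onset."""
        mask = (self.data["group"] == "case") & self.data["aao_years"].notna()
        return self.data[mask]

    def with_values(self, values: np.ndarray) -> "HarmonizedPanel":
        out = self.data.copy()
        out[list(PEPTIDES)] = np.asarray(values, dtype=float)
        return HarmonizedPanel(
            out,
            control_means=self.control_means,
            reference_proportions=self.reference_proportions,
            n_zero_filtered=self.n_zero_filtered,
            provenance=dict(self.provenance),
        )
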