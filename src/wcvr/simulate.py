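"""Synthetic multi-cohort amyloid-beta peptide panel generator.

Emulates the statistical structure of multi-assay PSEN1 cell-model datasets:

* five peptides with strongly unequal control abundances (Ab40 dominant,
  Ab43 rarest),
* per-cohort multiplicative assay biases (each assay/site measures each
  peptide with its own systematic gain),
* a familial-AD effect that shifts Ab37/Ab38/Ab40 down and Ab42/Ab43 up
  relative to controls, scaled per case by a severity factor so mutations
  differ in aggressiveness,
* heavy class imbalance (few control lines), technical replicates per line,
* an age-at-onset (AAO) that is noisily linear in a planted peptide-ratio
  biomarker,
* optional dropout of single measurements to zero, exercising the
  zero-removal filter.

Concentration noise is multiplicative lognormal: assay concentrations are
strictly positive and errors scale with signal.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import PeptidePanel
from .peptides import PEPTIDES
from .ratios import RatioSpec, short_long_spec


class ConfigurationError(ValueError):
    """Raised for invalid simulation configurations."""


#: Control relative abundances: Ab40 dominant, Ab38 ~ Ab37 > Ab42 >> Ab43.
DEFAULT_CONTROL_PROFILE: tuple[float, ...] = (0.13, 0.15, 0.60, 0.10, 0.02)

#: Multiplicative case effect at severity 1: short species down, long up.
DEFAULT_EFFECT_PROFILE: tuple[float, ...] = (0.70, 0.80, 0.85, 1.80, 2.50)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    ``assay_bias`` is one positive 5-vector per cohort; if ``None``, biases
    are drawn log-uniformly on [0.5, 2] from ``seed`` (cohort 0 is unbiased
    and serves as the reference cohort). ``planted_spec`` defines the ratio
    whose value on the noise-free, bias-free peptide vector sets each case's
    AAO via ``aao_intercept + aao_slope * value``.
    """

    n_cohorts: int = 3
    n_controls: int = 3
    n_cases: int = 40
    n_replicates: int = 3
    control_abundance_profile: tuple[float, ...] = DEFAULT_CONTROL_PROFILE
    assay_bias: list[tuple[float, ...]] | None = None
    effect_profile: tuple[float, ...] = DEFAULT_EFFECT_PROFILE
    severity_range: tuple[float, float] = (0.5, 1.5)
    planted_spec: RatioSpec = field(default_factory=short_long_spec)
    aao_intercept: float = 20.0
    aao_slope: float = 8.0
    noise_cv: float = 0.1
    aao_noise_sd: float = 3.0
    zero_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cohorts", "n_controls", "n_cases", "n_replicates"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be a positive integer")
        prof = np.asarray(self.control_abundance_profile, dtype=float)
        if prof.shape != (5,) or (prof <= 0).any():
            raise ConfigurationError(
                "control_abundance_profile must be 5 strictly positive fractions"
            )
        if abs(prof.sum() - 1.0) > 1e-12:
            raise ConfigurationError(
                f"control_abundance_profile must sum to 1 (got {prof.sum()!r})"
            )
        eff = np.asarray(self.effect_profile, dtype=float)
        if eff.shape != (5,) or (eff <= 0).any():
            raise ConfigurationError("effect_profile must be 5 positive multipliers")
        if self.assay_bias is not None:
            bias = np.asarray(self.assay_bias, dtype=float)
            if bias.shape != (self.n_cohorts, 5) or (bias <= 0).any():
                raise ConfigurationError(
                    "assay_bias must be one positive 5-vector per cohort"
                )
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        if not (0 <= self.zero_rate < 1):
            raise ConfigurationError("zero_rate must lie in [0, 1)")
        if self.aao_noise_sd < 0:
            raise ConfigurationError("aao_noise_sd must be >= 0")
        lo, hi = self.severity_range
        if not (0 < lo <= hi):
            raise ConfigurationError("severity_range must satisfy 0 < lo <= hi")

    # -- JSON round-trip --------------------------------------------------
    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["planted_spec"] = self.planted_spec.to_dict()
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        d["planted_spec"] = RatioSpec.from_dict(d["planted_spec"])
        for key in ("control_abundance_profile", "effect_profile", "severity_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("assay_bias") is not None:
            d["assay_bias"] = [tuple(b) for b in d["assay_bias"]]
        return cls(**d)


def _lognormal_sigma(cv: float) -> float:
    # CV of a lognormal with log-sd sigma is sqrt(exp(sigma^2) - 1)
    return float(np.sqrt(np.log1p(cv**2)))


def generate_cohorts(config: SimulationConfig) -> PeptidePanel:
    """Simulate a multi-cohort peptide panel under ``config``.

    Returns a :class:`PeptidePanel` with
    ``n_cohorts * (n_controls + n_cases) * n_replicates`` rows. Identical
    configurations (including seed) produce identical panels.
    """
    rng = np.random.default_rng(config.seed)
    profile = np.asarray(config.control_abundance_profile, dtype=float)
    effect = np.asarray(config.effect_profile, dtype=float)
    sigma = _lognormal_sigma(config.noise_cv)

    if config.assay_bias is not None:
        biases = np.asarray(config.assay_bias, dtype=float)
    else:
        biases = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=(config.n_cohorts, 5)))
        biases[0] = 1.0  # reference cohort measured without bias

    rows: list[dict] = []
    for ci in range(config.n_cohorts):
        cohort = f"cohort{ci}"
        bias = biases[ci]
        for si in range(config.n_controls + config.n_cases):
            is_case = si >= config.n_controls
            sample_id = f"{cohort}-{'case' if is_case else 'ctrl'}{si}"
            total = 1000.0 * np.exp(rng.normal(0.0, 0.3))
            if is_case:
                severity = rng.uniform(*config.severity_range)
                biology = profile * effect**severity
                planted = config.planted_spec.evaluate(biology)
                aao = (
                    config.aao_intercept
                    + config.aao_slope * planted
                    + rng.normal(0.0, config.aao_noise_sd)
                )
                codon = int(rng.integers(60, 450))
                mutation = f"p{codon}{chr(65 + int(rng.integers(0, 26)))}"
            else:
                biology = profile
                aao, codon, mutation = np.nan, None, None
            expected = total * biology * bias
            for ri in range(config.n_replicates):
                noise = np.exp(rng.normal(0.0, sigma, size=5)) if sigma > 0 else 1.0
                values = expected * noise
                if config.zero_rate > 0:
                    values = np.where(
                        rng.random(5) < config.zero_rate, 0.0, values
                    )
                rows.append(
                    {
                        "sample_id": sample_id,
                        "cohort": cohort,
                        "replicate": f"rep{ri}",
                        "group": "case" if is_case else "control",
                        "mutation": mutation,
                        "codon": codon,
                        "aao_years": aao,
                        **dict(zip(PEPTIDES, values)),
                    }
                )
    return PeptidePanel(pd.DataFrame(rows))
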