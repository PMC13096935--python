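"""Ratio biomarkers over amyloid-beta peptide panels.

A ratio biomarker assigns each peptide to the numerator, the denominator or
neither, with a non-negative weight; the biomarker value for a sample is

    sum_{i in X1} k_i * x_i  /  sum_{j in X2} k_j * x_j

where X1 (numerator) and X2 (denominator) are disjoint non-empty peptide
sets. The classical ratios (Ab42/40, Ab37/42, short/long) are special cases
with unit weights; the weighted composite value ratio (wCVR) lets a search
algorithm pick sides and weights.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .peptides import PEPTIDES


class RatioSpecError(ValueError):
    """Raised for ratio specifications violating the side constraints."""


@dataclass(frozen=True)
class RatioSpec:
    """A signed-weight assignment of peptides to numerator/denominator.

    Weights are stored non-negative; side membership carries the sign in
    serialized form (denominator weights are written as negative
    percentages, mirroring the usual reporting convention).
    """

    name: str
    numerator: Mapping[str, float]
    denominator: Mapping[str, float]

    def __post_init__(self) -> None:
        num = {p: float(w) for p, w in self.numerator.items() if float(w) != 0.0}
        den = {p: float(w) for p, w in self.denominator.items() if float(w) != 0.0}
        for side, label in ((num, "numerator"), (den, "denominator")):
            for p, w in side.items():
                if p not in PEPTIDES:
                    raise RatioSpecError(f"{label} contains unknown peptide {p!r}")
                if w < 0:
                    raise RatioSpecError(f"{label} weight for {p} must be >= 0")
        if not num or not den:
            raise RatioSpecError(
                f"spec {self.name!r}: numerator and denominator must each contain "
                "at least one peptide with positive weight"
            )
        if set(num) & set(den):
            raise RatioSpecError(
                f"spec {self.name!r}: numerator and denominator sets overlap: "
                f"{sorted(set(num) & set(den))}"
            )
        object.__setattr__(self, "numerator", num)
        object.__setattr__(self, "denominator", den)

    # -- weight vectors ---------------------------------------------------
    def weight_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """(numerator, denominator) weight arrays in PEPTIDES order."""
        num = np.array([self.numerator.get(p, 0.0) for p in PEPTIDES])
        den = np.array([self.denominator.get(p, 0.0) for p in PEPTIDES])
        return num, den

    def signed_weights(self) -> dict[str, float]:
        """Signed normalized percentages: numerator positive, denominator
        negative; each side sums to +/-100."""
        spec = normalize_spec(self)
        out: dict[str, float] = {}
        for p in PEPTIDES:
            if p in spec.numerator:
                out[p] = spec.numerator[p]
            elif p in spec.denominator:
                out[p] = -spec.denominator[p]
            else:
                out[p] = 0.0
        return out

    def evaluate(self, values: np.ndarray | Sequence[float]) -> np.ndarray | float:
        """Ratio value(s) for a 5-vector or (n, 5) array in PEPTIDES order."""
        num_w, den_w = self.weight_vectors()
        arr = np.asarray(values, dtype=float)
        num = arr @ num_w
        den = arr @ den_w
        if np.any(np.asarray(den) <= 0):
            raise RatioSpecError(
                f"spec {self.name!r}: non-positive denominator encountered"
            )
        return num / den

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        """Signed-weight JSON form (denominator negative). Raw weights are
        preserved so that a round-tripped spec scores identically; use
        :meth:`signed_weights` for the normalized percent presentation."""
        weights = {p: 0.0 for p in PEPTIDES}
        weights.update(self.numerator)
        weights.update({p: -w for p, w in self.denominator.items()})
        return {"name": self.name, "weights": weights}

    @classmethod
    def from_dict(cls, d: Mapping) -> "RatioSpec":
        num = {p: w for p, w in d["weights"].items() if w > 0}
        den = {p: -w for p, w in d["weights"].items() if w < 0}
        return cls(name=d.get("name", "ratio"), numerator=num, denominator=den)


@dataclass
class BiomarkerScores:
    """Per-sample biomarker values plus the abnormal-direction orientation.

    ``orientation`` is ``"higher"`` when cases tend to score above controls
    (case median > control median) and ``"lower"`` otherwise; ``None`` when
    the panel lacked one of the classes.
    """

    spec: RatioSpec
    scores: np.ndarray
    orientation: str | None = None

    def oriented(self) -> np.ndarray:
        """Scores transformed so that higher always means more abnormal."""
        if self.orientation == "lower":
            return -self.scores
        return self.scores


def resolve_orientation(scores: np.ndarray, is_case: np.ndarray) -> str | None:
    """Abnormal direction: sign of (case median - control median)."""
    is_case = np.asarray(is_case, dtype=bool)
    if not is_case.any() or is_case.all():
        return None
    case_med = float(np.median(scores[is_case]))
    ctrl_med = float(np.median(scores[~is_case]))
    return "higher" if case_med >= ctrl_med else "lower"


def compute_ratio(spec: RatioSpec, panel) -> BiomarkerScores:
    """Score every row of a (harmonized, usually reference-rescaled) panel.

    ``panel`` is anything with ``.values`` (n, 5) in PEPTIDES order and
    ``.is_case``; values must be strictly positive.
    """
    scores = np.asarray(spec.evaluate(panel.values), dtype=float)
    orientation = resolve_orientation(scores, panel.is_case)
    return BiomarkerScores(spec=spec, scores=scores, orientation=orientation)


def normalize_spec(spec: RatioSpec) -> RatioSpec:
    """Rescale each side's weights to sum to 100 (percent convention).

    Scores from the normalized spec are a fixed positive multiple of the
    original's, so every scale-invariant evaluation metric is unchanged.
    """
    num_total = sum(spec.numerator.values())
    den_total = sum(spec.denominator.values())
    return replace(
        spec,
        numerator={p: 100.0 * w / num_total for p, w in spec.numerator.items()},
        denominator={p: 100.0 * w / den_total for p, w in spec.denominator.items()},
    )


# -- named benchmark ratios ----------------------------------------------

def short_long_spec() -> RatioSpec:
    """Ab(37+38+40)/(42+43) with unit weights; on reference-rescaled data
    this reproduces natural-abundance weighting."""
    return RatioSpec(
        "short/long",
        numerator={"Ab37": 1.0, "Ab38": 1.0, "Ab40": 1.0},
        denominator={"Ab42": 1.0, "Ab43": 1.0},
    )


def benchmark_specs() -> list[RatioSpec]:
    """The four reference ratios used throughout the field."""
    return [
        RatioSpec("Ab42/40", numerator={"Ab42": 1.0}, denominator={"Ab40": 1.0}),
        RatioSpec("Ab40/42", numerator={"Ab40": 1.0}, denominator={"Ab42": 1.0}),
        RatioSpec("Ab37/42", numerator={"Ab37": 1.0}, denominator={"Ab42": 1.0}),
        short_long_spec(),
    ]


def enumerate_ratio_specs(peptides: Iterable[str] = PEPTIDES) -> list[RatioSpec]:
    """Every ordered pair of disjoint non-empty peptide subsets, unit weights.

    For n peptides there are 3^n - 2*2^n + 1 such ratios (each peptide is in
    the numerator, the denominator or unused; subtract assignments with an
    empty side). For the five-peptide panel this yields 180 specs.
    """
    peptides = list(peptides)
    if len(set(peptides)) < 2:
        raise RatioSpecError("need at least 2 distinct peptides to form a ratio")
    specs = []
    for assignment in product((0, 1, 2), repeat=len(peptides)):
        num = [p for p, a in zip(peptides, assignment) if a == 1]
        den = [p for p, a in zip(peptides, assignment) if a == 2]
        if not num or not den:
            continue
        name = "+".join(num) + "/" + "+".join(den)
        specs.append(
            RatioSpec(name, numerator={p: 1.0 for p in num},
                      denominator={p: 1.0 for p in den})
        )
    return specs


def specs_to_frame(specs: Sequence[RatioSpec]) -> pd.DataFrame:
    """Signed-percentage weight table, one row per spec (reporting helper)."""
    rows = [{"name": s.name, **s.signed_weights()} for s in specs]
    return pd.DataFrame(rows).set_index("name")
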