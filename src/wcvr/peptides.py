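"""Canonical amyloid-beta peptide names and name normalization.

The analysis works on the five C-terminally distinct species measured in
conditioned media from PSEN1 cell models: Ab37, Ab38, Ab40, Ab42 and Ab43.
Longer species (Ab42, Ab43) are aggregation-prone and shift up in familial
Alzheimer's disease; shorter species shift down.
"""

from __future__ import annotations

PEPTIDES: tuple[str, ...] = ("Ab37", "Ab38", "Ab40", "Ab42", "Ab43")

#: species sometimes present in published multiplex panels but outside the
#: five-peptide analysis; their presence in an input file is an error rather
#: than something to silently drop.
UNSUPPORTED_PEPTIDES: tuple[str, ...] = ("Ab39",)

_ALIAS_PREFIXES = ("ab", "abeta", "aβ", "amyloid-beta", "amyloidbeta")


def canonical_peptide(name: str) -> str:
    """Map an input peptide label (e.g. ``"Aβ42"``, ``"abeta40"``) to its
    canonical ``AbNN`` form.

    Raises ``ValueError`` for labels that do not resolve to one of the five
    supported peptides, with a dedicated message for Ab39.
    """
    raw = str(name).strip()
    low = raw.lower().replace("_", "").replace(" ", "")
    digits = "".join(ch for ch in low if ch.isdigit())
    stem = "".join(ch for ch in low if not ch.isdigit())
    if stem in _ALIAS_PREFIXES and digits:
        candidate = f"Ab{digits}"
        if candidate in PEPTIDES:
            return candidate
        if candidate in UNSUPPORTED_PEPTIDES:
            raise ValueError(
                f"peptide {raw!r} is not part of the five-peptide analysis "
                f"(supported: {', '.join(PEPTIDES)}); drop the column before loading"
            )
    raise ValueError(
        f"unknown peptide label {raw!r}; expected one of {', '.join(PEPTIDES)}"
    )
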