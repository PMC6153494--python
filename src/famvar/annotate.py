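"""Damaging-variant classification, minor-allele orientation, control-AF
resolution and allele-frequency tiering."""

from __future__ import annotations

from enum import Enum
from typing import Optional

from .model import HIGH_IMPACT, MISSING, Consequence, VariantRecord

__all__ = [
    "AFTier",
    "orient_to_minor_allele",
    "is_damaging",
    "control_af",
    "classify_af_tier",
]


class AFTier(str, Enum):
    VERY_RARE = "very_rare"
    RARE = "rare"
    COMMON = "common"


def _deciding_af(v: VariantRecord) -> Optional[float]:
    # panel precedence for the orientation decision
    for af in (v.af_paj, v.af_aj, v.af_nfe):
        if af is not None:
            return af
    return None


def orient_to_minor_allele(v: VariantRecord) -> VariantRecord:
    """Flip genotypes and AFs when the reference genome carries the minor allele.

    If the deciding panel AF exceeds 0.5, called dosages map 0<->2, every
    panel AF maps af -> 1-af, and the record is flagged ``flipped``
    (flipping again restores the original).  With all AFs missing the
    record is returned unchanged, flagged ``unoriented``.
    """
    af = _deciding_af(v)
    if af is None:
        v.flags.add("unoriented")
        return v
    if af <= 0.5:
        return v
    called = v.dosages != MISSING
    v.dosages[called] = 2 - v.dosages[called]
    for attr in ("af_aj", "af_nfe", "af_paj", "af_aj_wgs"):
        val = getattr(v, attr)
        if val is not None:
            setattr(v, attr, 1.0 - val)
    v.ad_ref, v.ad_alt = v.ad_alt, v.ad_ref
    v.flags.symmetric_difference_update({"flipped"})
    return v


def is_damaging(consequence: Consequence, carol: Optional[str] = None,
                cadd: Optional[float] = None) -> bool:
    """Damaging call: high-impact classes unconditionally; missense only when
    predicted damaging with CADD >= 20."""
    consequence = Consequence(consequence)
    if consequence in HIGH_IMPACT:
        return True
    if consequence is Consequence.MISSENSE:
        if carol is None or cadd is None:
            return False
        return carol == "damaging" and cadd >= 20.0
    return False


def control_af(v: VariantRecord, context: str = "filtering") -> float:
    """Resolve the control allele frequency as the max over reference panels.

    Missing panels are treated as absent, never as zero.  In the
    ``genedrop`` context a missing exome AJ frequency is substituted by the
    AJ whole-genome frequency before taking the max.  With every source
    missing, returns 0 and flags the record ``af_unknown``.
    """
    if context not in ("filtering", "genedrop"):
        raise ValueError(f"unknown context {context!r}")
    af_aj = v.af_aj
    if context == "genedrop" and af_aj is None:
        af_aj = v.af_aj_wgs
    sources = [af for af in (af_aj, v.af_nfe, v.af_paj) if af is not None]
    if not sources:
        v.flags.add("af_unknown")
        return 0.0
    return max(sources)


def classify_af_tier(af: float) -> AFTier:
    """Tier an allele frequency: very rare (<0.005), rare (<0.05), common (>0.05).

    Boundary values (exactly 0.005 or 0.05) fall in the rare tier.
    """
    if not 0.0 <= af <= 1.0:
        raise ValueError(f"allele frequency {af} outside [0, 1]")
    if af < 0.005:
        return AFTier.VERY_RARE
    if af <= 0.05:
        return AFTier.RARE
    return AFTier.COMMON
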