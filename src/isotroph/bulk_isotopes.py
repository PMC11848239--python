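"""Delta-notation arithmetic and consumer-vs-resource shift bookkeeping.

delta X = (R_sample - R_standard) / R_standard * 1000, in per mil.

A consumer feeding one trophic level above its resource is typically
0.5-1 per-mil enriched in 13C; detritus-based feeding produces larger
"detrital" shifts. The band is a descriptive tag only — no inference
hangs on it — and is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

from .errors import DomainError

#: Conventional per-trophic-level 13C enrichment band, per mil.
DEFAULT_TROPHIC_BAND = (0.5, 1.0)


@dataclass(frozen=True)
class DeltaValue:
    """An isotope delta value in per mil for one element (C13 or N15)."""

    value: float
    element: str

    def __post_init__(self) -> None:
        if self.element not in ("C13", "N15"):
            raise DomainError(f"element must be 'C13' or 'N15', got {self.element!r}")
        if not math.isfinite(self.value):
            raise DomainError("delta value must be finite")


def delta_from_ratios(r_sample: float, r_standard: float, element: str = "C13") -> DeltaValue:
    """Delta value from raw heavy/light isotope ratios."""
    if r_standard <= 0:
        raise DomainError(f"r_standard must be > 0, got {r_standard}")
    if r_sample < 0:
        raise DomainError(f"r_sample must be >= 0, got {r_sample}")
    return DeltaValue((r_sample - r_standard) / r_standard * 1000.0, element)


def ratio_from_delta(delta: DeltaValue, r_standard: float) -> float:
    """Invert :func:`delta_from_ratios`: recover R_sample."""
    if r_standard <= 0:
        raise DomainError(f"r_standard must be > 0, got {r_standard}")
    return r_standard * (1.0 + delta.value / 1000.0)


def trophic_shift(consumer: DeltaValue, resource: DeltaValue) -> float:
    """Consumer-minus-resource delta difference, per mil (enrichment positive)."""
    if consumer.element != resource.element:
        raise DomainError(
            f"element mismatch: consumer {consumer.element}, resource {resource.element}"
        )
    return consumer.value - resource.value


def classify_shift(shift: float, band: tuple[float, float] = DEFAULT_TROPHIC_BAND) -> str:
    """Tag a 13C shift relative to the per-trophic-level enrichment band.

    Returns ``"sub-trophic"`` below the band, ``"non-detrital-range"``
    inside it (inclusive), ``"detrital-range"`` above — shifts above the
    band are characteristic of detritus-based energy channels.
    """
    lo, hi = band
    if lo > hi:
        raise DomainError(f"band must be ordered, got {band}")
    if shift < lo:
        return "sub-trophic"
    if shift <= hi:
        return "non-detrital-range"
    return "detrital-range"
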