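"""Stable carbon isotope utilities: del notation and upcore trend calls.

delta-13C is the per-mil deviation of a sample's 13C/12C ratio from the
Pee Dee Belemnite standard. In residual methane, enrichment toward the
surface (heavier methane shallower) indicates net anaerobic oxidation -
methanotrophs prefer the light isotope - while depletion toward the surface
indicates net methanogenesis.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .profiles import IsotopeProfile

#: conventional 13C/12C ratio of the VPDB standard
R_VPDB = 0.0112372


def delta13c(R_sample: float, R_standard: float = R_VPDB) -> float:
    """del notation: delta = (R_sample / R_standard - 1) * 1000, in per-mil."""
    if R_sample <= 0 or R_standard <= 0:
        raise DomainError("isotope ratios must be positive")
    return (R_sample / R_standard - 1.0) * 1000.0


def ratio_from_delta(delta: float, R_standard: float = R_VPDB) -> float:
    """Inverse of :func:`delta13c`: the 13C/12C ratio with the given del value."""
    if R_standard <= 0:
        raise DomainError("standard ratio must be positive")
    ratio = (delta / 1000.0 + 1.0) * R_standard
    if ratio <= 0:
        raise DomainError(f"delta {delta} per-mil implies a non-positive ratio")
    return ratio


@dataclass(frozen=True)
class TrendCall:
    trend: str  # enrichment_upcore | depletion_upcore | indeterminate
    interpretation: str
    slope_permil_per_cm: float | None
    span_change_permil: float | None
    reason: str = ""


def classify_trend(profile: IsotopeProfile, min_span_permil: float = 1.0) -> TrendCall:
    """Call the upcore delta-13C trend of methane.

    The call is the sign of the least-squares slope of delta vs. depth,
    subject to a minimum change over the profile span (default 1 per-mil) to
    avoid reading noise as signal. A positive slope (lighter methane
    shallower) is depletion upcore -> net methanogenesis; a negative slope
    (heavier shallower) is enrichment upcore -> net methane oxidation.

    With four or more measured depths, a call that flips when the single
    shallowest point is dropped is refused as indeterminate: a lone surface
    excursion can reflect aerobic oxidation at the interface rather than a
    trend in the anaerobic zone.
    """
    mask = profile.measured_mask
    x = profile.grid.x[mask]
    d = profile.delta13c[mask]
    call = _slope_call(x, d, min_span_permil)
    if call.trend != "indeterminate" and x.size >= 4:
        sub = _slope_call(x[1:], d[1:], min_span_permil)
        if sub.trend != call.trend:
            return TrendCall(
                "indeterminate",
                "no robust trend",
                call.slope_permil_per_cm,
                call.span_change_permil,
                reason="call depends on a single surface point",
            )
    return call


def _slope_call(x: np.ndarray, d: np.ndarray, min_span_permil: float) -> TrendCall:
    if x.size < 3:
        return TrendCall("indeterminate", "no robust trend", None, None,
                         reason=f"only {x.size} measured depth(s); need >= 3")
    slope, _ = np.polyfit(x, d, 1)
    span = float(slope * (x[-1] - x[0]))
    if abs(span) < min_span_permil:
        return TrendCall("indeterminate", "no robust trend", float(slope), span,
                         reason=f"delta change over span ({span:.2f} per-mil) below {min_span_permil} per-mil floor")
    if slope > 0:  # delta increases with depth: surface is isotopically lighter
        return TrendCall("depletion_upcore", "net methanogenesis", float(slope), span)
    return TrendCall("enrichment_upcore", "net methane oxidation", float(slope), span)
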