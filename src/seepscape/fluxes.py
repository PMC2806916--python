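"""Diffusive fluxes, depth-integrated rates, and consistency checks.

Flux sign convention: positive is upward, out of the sediment. With depth x
positive downward, the diffusive flux is J = phi * D_s * dC/dx, so a solute
decreasing with depth (sulfate under an active mat) yields a negative flux:
transport into the sediment. Depth integration of a volumetric rate uses the
trapezoid rule with nmol cm^-3 d^-1 * cm = 0.01 mmol m^-2 d^-1.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ValidationError
from .profiles import RateProfile, SoluteProfile

_FLUX_UNIT = 86400.0 * 1e4 * 1e-3  # (cm^2 s^-1 * mM / cm) -> mmol m^-2 d^-1
RATE_INTEGRAL_UNIT = 0.01  # nmol cm^-3 d^-1 * cm -> mmol m^-2 d^-1

#: methane outgasses to about this value (mM) at 1 atm; higher shipboard
#: readings are lower bounds on in-situ concentration
METHANE_SATURATION_MM = 1.2

PROCESS_FOR_SOLUTE = {"sulfate": "sulfate_reduction", "methane": "methane_oxidation"}


@dataclass(frozen=True)
class FluxResult:
    """Diffusive flux across the top of a profile, mmol m^-2 d^-1, positive upward."""

    solute: str
    flux: float
    depth_pair: tuple[float, float]

    def __post_init__(self):
        if not math.isfinite(self.flux):
            raise ValidationError("flux must be finite")
        if not self.depth_pair[0] < self.depth_pair[1]:
            raise ValidationError("depth_pair must be strictly increasing")


@dataclass(frozen=True)
class IntegratedRate:
    """Depth-integrated volumetric rate, mmol m^-2 d^-1."""

    process: str
    value: float
    depth_range: tuple[float, float]


def diffusive_flux_top(
    profile: SoluteProfile,
    phi: float,
    D_s: float,
    porosity_correction: bool = True,
) -> FluxResult:
    """Fick's-law flux from the first two depths of a concentration profile.

    Parameters
    ----------
    profile : concentration profile; the gradient uses its first two nodes
        (interval midpoints when built from core sections).
    phi : porosity entering the flux (set ``porosity_correction=False`` to
        report the free-solution flux phi=1).
    D_s : sediment diffusivity in cm^2 s^-1.
    """
    x = profile.grid.x
    c = profile.concentration
    if x.size < 2:
        raise ValidationError("flux needs at least two depths")
    dx = x[1] - x[0]
    if dx == 0:
        raise DomainError("zero depth spacing between the first two depths")
    phi_eff = phi if porosity_correction else 1.0
    grad = (c[1] - c[0]) / dx  # mM / cm
    flux = phi_eff * D_s * grad * _FLUX_UNIT
    return FluxResult(profile.solute, float(flux), (float(x[0]), float(x[1])))


def depth_integrated_rate(
    rates: RateProfile,
    z_min: float = 0.0,
    z_max: float = 25.0,
    process: str = "sulfate_reduction",
) -> IntegratedRate:
    """Trapezoidal depth integral of R(x) over [z_min, z_max].

    Depths outside the measured profile are treated as zero-rate (gaps
    zero-filled); an integration window that misses the profile entirely is
    an error. The default window caps at 25 cm, the deepest rate data the
    surficial-sediment integrations use.
    """
    if z_min >= z_max:
        raise ValidationError("z_min must be < z_max")
    x, r = rates.grid.x, rates.rate
    if z_max <= x[0] or z_min >= x[-1]:
        raise ValidationError(
            f"integration window ({z_min}, {z_max}) does not overlap the rate profile"
        )
    lo, hi = max(z_min, x[0]), min(z_max, x[-1])
    inside = (x > lo) & (x < hi)
    xs = np.concatenate(([lo], x[inside], [hi]))
    rs = np.concatenate(([np.interp(lo, x, r)], r[inside], [np.interp(hi, x, r)]))
    value = float(np.trapezoid(rs, xs)) * RATE_INTEGRAL_UNIT
    return IntegratedRate(process, value, (float(z_min), float(z_max)))


@dataclass(frozen=True)
class ConsistencyReport:
    """Comparison of a top diffusive flux with a depth-integrated rate."""

    solute: str
    process: str
    abs_flux: float
    integrated_rate: float
    ratio: float
    difference: float
    flag: str  # agree | rate_underestimated | rate_overestimated


def flux_rate_consistency(
    flux: FluxResult,
    rate: IntegratedRate,
    agreement_factor: float = 3.0,
) -> ConsistencyReport:
    """Flag whether a measured rate accounts for the observed flux.

    Agreement means |flux|/rate within [1/agreement_factor, agreement_factor];
    a ratio above flags the rate as underestimated, below as overestimated.
    Both zero is reported as agreement with ratio 1 by convention.
    """
    expected = PROCESS_FOR_SOLUTE.get(flux.solute)
    if expected != rate.process:
        raise ValidationError(
            f"solute {flux.solute!r} pairs with {expected!r}, not {rate.process!r}"
        )
    if agreement_factor <= 1:
        raise DomainError("agreement factor must exceed 1")
    af = abs(flux.flux)
    if af == 0 and rate.value == 0:
        ratio = 1.0
    elif rate.value == 0:
        ratio = math.inf
    else:
        ratio = af / rate.value
    if 1.0 / agreement_factor <= ratio <= agreement_factor:
        flag = "agree"
    elif ratio > agreement_factor:
        flag = "rate_underestimated"
    else:
        flag = "rate_overestimated"
    return ConsistencyReport(
        flux.solute, rate.process, af, rate.value, ratio, af - rate.value, flag
    )


def mrna_persistence_time(depth_offset_cm: float, sedimentation_rate_cm_kyr: float):
    """Years a transcript must persist to be buried `depth_offset_cm` below
    the depth where its process stops, at the given sedimentation rate.

    Returns (exact_years, floored_whole_years).
    """
    if sedimentation_rate_cm_kyr <= 0:
        raise DomainError("sedimentation rate must be positive")
    if depth_offset_cm < 0:
        raise DomainError("depth offset must be non-negative")
    years = depth_offset_cm / sedimentation_rate_cm_kyr * 1000.0
    return years, math.floor(years)


def flag_saturation(profile: SoluteProfile, saturation_mM: float = METHANE_SATURATION_MM) -> np.ndarray:
    """Per-depth flags, True where a methane reading exceeds atmospheric
    saturation and is therefore only a lower bound (strict inequality)."""
    return profile.concentration > saturation_mM
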