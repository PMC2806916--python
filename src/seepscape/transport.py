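"""1-D steady-state porewater reaction-transport model.

The model balances, at every depth x (cm below seafloor, positive down),

    d/dx( phi * D_s * dC/dx )  -  d( phi * omega * C )/dx
        + phi * alpha * (C_ow - C)  -  phi * R  =  0

with C the porewater concentration (mM), phi porosity, D_s the sediment
diffusivity, omega the burial (sedimentation + compaction) velocity, alpha
the nonlocal bioirrigation exchange coefficient toward the overlying-water
concentration C_ow, and R the volumetric consumption rate of the solute.
The four terms are molecular diffusion, burial advection, bioirrigation,
and reaction.

The equation is discretized with second-order central finite differences on
the node grid, giving a tridiagonal linear system: Dirichlet C(0)=C_ow at
the sediment-water interface and either a fixed value or a zero-gradient
(mirrored ghost node) condition at the bottom of the domain. Because the
steady state is linear in R, the inverse problem - piecewise-constant layer
rates from an observed concentration profile - reduces to linear least
squares on precomputed layer response profiles.

Internal unit system: cm, days, mM (== micromol cm^-3). D_O is accepted in
cm^2 s^-1 and omega in cm kyr^-1, the units these quantities are reported
in, and converted on entry.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import solve_banded

from .errors import DomainError, EstimationError, NumericalError, ValidationError
from .profiles import DepthGrid, RateProfile, SoluteProfile

SECONDS_PER_DAY = 86400.0
DAYS_PER_KYR = 1000.0 * 365.25

#: default sulfate background threshold (mM) used for penetration depth
DEFAULT_PENETRATION_THRESHOLD_MM = 0.7


def effective_diffusivity(phi: float, D_O: float) -> float:
    """Sediment (tortuosity-corrected) diffusivity D_s = D_O / (1 - ln(phi^2)).

    Parameters
    ----------
    phi : porosity, in (0, 1].
    D_O : molecular diffusivity in free solution, cm^2 s^-1.

    Returns D_s in the same units as D_O; D_s <= D_O with equality iff phi == 1.
    """
    phi_arr = np.asarray(phi, dtype=float)
    if np.any(phi_arr <= 0) or np.any(phi_arr > 1):
        raise DomainError(f"porosity must lie in (0, 1], got {phi}")
    if np.any(np.asarray(D_O) <= 0):
        raise DomainError("molecular diffusivity must be positive")
    out = D_O / (1.0 - np.log(phi_arr**2))
    return float(out) if np.isscalar(phi) else out


@dataclass(frozen=True)
class TransportSystem:
    """Geometry, physics, and boundary conditions of the steady-state model.

    bottom_boundary is either the string "zero_gradient" (no diffusive flux
    through the core bottom, the default) or a float fixing the bottom
    concentration in mM. Optional upward porewater advection (cm d^-1,
    positive upward) is available but off by default; only burial is printed
    in the governing equation.
    """

    grid: DepthGrid
    porosity: float | np.ndarray = 0.8
    molecular_diffusivity: float = 5e-6  # D_O, cm^2 s^-1
    sedimentation_rate: float = 0.0  # omega, cm kyr^-1
    bioirrigation: float | np.ndarray = 0.0  # alpha, d^-1
    overlying_concentration: float = 28.0  # C_ow, mM
    bottom_boundary: str | float = "zero_gradient"
    tortuosity: bool = True
    upward_velocity_cm_d: float = 0.0

    def __post_init__(self):
        if self.grid.n < 3:
            raise ValidationError("transport grid needs at least 3 nodes")
        if self.grid.x[0] != 0.0:
            raise ValidationError("transport grid must start at the sediment-water interface (0 cm)")
        phi = np.broadcast_to(np.asarray(self.porosity, dtype=float), self.grid.x.shape).copy()
        if np.any(phi <= 0) or np.any(phi > 1):
            raise ValidationError("porosity must lie in (0, 1]")
        alpha = np.broadcast_to(np.asarray(self.bioirrigation, dtype=float), self.grid.x.shape).copy()
        if np.any(alpha < 0):
            raise ValidationError("bioirrigation coefficient must be >= 0")
        if self.molecular_diffusivity <= 0:
            raise ValidationError("molecular diffusivity must be positive")
        if self.sedimentation_rate < 0:
            raise ValidationError("sedimentation rate must be >= 0")
        if isinstance(self.bottom_boundary, str) and self.bottom_boundary != "zero_gradient":
            raise ValidationError("bottom_boundary must be 'zero_gradient' or a fixed mM value")
        object.__setattr__(self, "porosity", phi)
        object.__setattr__(self, "bioirrigation", alpha)

    @property
    def sediment_diffusivity(self) -> np.ndarray:
        """Per-node D_s in cm^2 d^-1 (tortuosity-corrected unless disabled)."""
        D = self.molecular_diffusivity * SECONDS_PER_DAY
        if self.tortuosity:
            return D / (1.0 - np.log(self.porosity**2))
        return D * np.ones_like(self.porosity)

    @property
    def burial_velocity(self) -> float:
        """omega in cm d^-1 (downward positive), net of any upward advection."""
        return self.sedimentation_rate / DAYS_PER_KYR - self.upward_velocity_cm_d


def solve_forward(sys: TransportSystem, rates: RateProfile) -> SoluteProfile:
    """Steady-state concentration profile for a given volumetric rate profile.

    Negative solution values are physically meaningful diagnostics (an
    imposed rate too large for the transport supply) and are returned
    unclipped.
    """
    if rates.grid.x.shape != sys.grid.x.shape or not np.allclose(rates.grid.x, sys.grid.x):
        raise ValidationError("rate profile is not defined on the transport grid")
    x = sys.grid.x
    n = x.size
    phi = sys.porosity
    Ds = sys.sediment_diffusivity
    w = phi * Ds  # diffusion conductance, cm^2 d^-1 weighted by porosity
    phi_omega = phi[0] * sys.burial_velocity  # constant phi*omega product (steady compaction)
    alpha = sys.bioirrigation
    R = rates.rate * 1e-3  # nmol cm^-3 d^-1 -> micromol cm^-3 d^-1 (mM * cm^3)
    C_ow = sys.overlying_concentration

    lower = np.zeros(n)
    diag = np.zeros(n)
    upper = np.zeros(n)
    rhs = np.zeros(n)

    # top boundary: Dirichlet at the sediment-water interface
    diag[0] = 1.0
    rhs[0] = C_ow

    h = np.diff(x)
    for i in range(1, n - 1):
        hm, hp = h[i - 1], h[i]
        w_m = 0.5 * (w[i - 1] + w[i])
        w_p = 0.5 * (w[i] + w[i + 1])
        vol = 0.5 * (hm + hp)
        a = w_m / (hm * vol)
        c = w_p / (hp * vol)
        adv = phi_omega / (hm + hp)  # central difference on d(phi*omega*C)/dx
        lower[i] = a + adv
        upper[i] = c - adv
        diag[i] = -(a + c) - phi[i] * alpha[i]
        rhs[i] = phi[i] * R[i] - phi[i] * alpha[i] * C_ow

    if isinstance(sys.bottom_boundary, str):  # zero gradient: mirrored ghost node
        hm = h[-1]
        a = w[-1] / hm**2  # ghost conductance symmetric, advection cancels
        lower[-1] = 2.0 * a
        diag[-1] = -2.0 * a - phi[-1] * alpha[-1]
        rhs[-1] = phi[-1] * R[-1] - phi[-1] * alpha[-1] * C_ow
    else:
        diag[-1] = 1.0
        rhs[-1] = float(sys.bottom_boundary)

    ab = np.zeros((3, n))
    ab[0, 1:] = upper[:-1]
    ab[1, :] = diag
    ab[2, :-1] = lower[1:]
    with np.errstate(all="ignore"):
        try:
            c = solve_banded((1, 1), ab, rhs)
        except Exception as exc:  # singular factorization
            raise NumericalError(f"steady-state system could not be solved: {exc}") from exc
    if not np.all(np.isfinite(c)):
        raise NumericalError("steady-state system is singular (non-finite solution)")
    return SoluteProfile(sys.grid, c, solute="modeled")


def equal_layers(sys: TransportSystem, n_layers: int) -> list[tuple[float, float]]:
    """Contiguous equal-thickness layer bounds covering the model domain."""
    edges = np.linspace(sys.grid.x[0], sys.grid.bottom, n_layers + 1)
    return [(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])]


@dataclass(frozen=True)
class InverseFit:
    """Result of a piecewise-constant rate inversion."""

    rates: RateProfile
    layer_bounds: list[tuple[float, float]]
    layer_rates: np.ndarray  # nmol cm^-3 d^-1 per layer
    residual_norm: float  # 2-norm of concentration residual, mM
    predicted: SoluteProfile = field(repr=False)


def fit_rates_inverse(
    sys: TransportSystem,
    observed: SoluteProfile,
    n_layers: int = 3,
    layer_bounds: Sequence[tuple[float, float]] | None = None,
) -> InverseFit:
    """Least-squares piecewise-constant rates reproducing an observed profile.

    The forward map is affine in the rate vector, so the fit is a single
    linear least-squares solve against precomputed unit-rate layer responses.
    Rates may come out negative (net production); no positivity constraint
    is imposed.
    """
    if n_layers < 1 or n_layers > sys.grid.n - 2:
        raise ValidationError("n_layers must be between 1 and the number of interior nodes")
    if observed.grid.x.shape != sys.grid.x.shape or not np.allclose(observed.grid.x, sys.grid.x):
        raise ValidationError("observed profile is not on the transport grid")
    bounds = list(layer_bounds) if layer_bounds is not None else equal_layers(sys, n_layers)
    if len(bounds) != n_layers:
        raise ValidationError("layer_bounds length must equal n_layers")

    base = solve_forward(sys, RateProfile(sys.grid, np.zeros(sys.grid.n))).concentration
    A = np.empty((sys.grid.n, n_layers))
    for k, (top, bottom) in enumerate(bounds):
        unit = RateProfile.from_layers(sys.grid, [(top, bottom, 1.0)])
        if not np.any(unit.rate):
            raise EstimationError(f"layer {k} ({top}-{bottom} cm) contains no grid nodes")
        A[:, k] = solve_forward(sys, unit).concentration - base
    r, _, rank, _ = np.linalg.lstsq(A, observed.concentration - base, rcond=None)
    if rank < n_layers:
        dead = [k for k in range(n_layers) if not np.any(np.abs(A[:, k]) > 0)]
        raise EstimationError(f"layer design is rank-deficient (rank {rank} < {n_layers}; layers {dead or 'collinear'})")
    layers = [(top, bottom, rk) for (top, bottom), rk in zip(bounds, r)]
    # reuse from_layers for the node profile, closing the half-open bottom layer
    rate_nodes = np.zeros(sys.grid.n)
    for (top, bottom), rk in zip(bounds, r):
        rate_nodes[(sys.grid.x >= top) & (sys.grid.x <= bottom)] = rk
    fitted = RateProfile(sys.grid, rate_nodes)
    predicted = solve_forward(sys, fitted)
    resid = float(np.linalg.norm(A @ r - (observed.concentration - base)))
    return InverseFit(fitted, bounds, np.asarray(r), resid, predicted)


@dataclass(frozen=True)
class PenetrationDepth:
    """Shallowest depth at which a solute falls to a background threshold.

    If the profile stays above the threshold over the whole domain,
    ``beyond_domain`` is True and ``depth_cm`` carries the domain bottom.
    """

    depth_cm: float
    beyond_domain: bool
    threshold_mM: float

    def __str__(self) -> str:
        if self.beyond_domain:
            return f">{self.depth_cm:g} cm (threshold {self.threshold_mM:g} mM not reached in domain)"
        return f"{self.depth_cm:g} cm"


def penetration_depth(profile: SoluteProfile, threshold: float = DEFAULT_PENETRATION_THRESHOLD_MM) -> PenetrationDepth:
    """Depth where the linearly interpolated concentration first falls to `threshold` (mM)."""
    if threshold <= 0:
        raise DomainError("penetration threshold must be positive")
    x = profile.grid.x
    c = profile.concentration
    if c[0] <= threshold:
        return PenetrationDepth(0.0, False, threshold)
    below = np.nonzero(c <= threshold)[0]
    if below.size == 0:
        return PenetrationDepth(float(x[-1]), True, threshold)
    i = below[0]
    x0, x1, c0, c1 = x[i - 1], x[i], c[i - 1], c[i]
    depth = x0 + (c0 - threshold) * (x1 - x0) / (c0 - c1)
    return PenetrationDepth(float(depth), False, threshold)
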