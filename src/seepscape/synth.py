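"""Seeded synthetic cores and clone libraries.

The generators emulate the statistical structure of a seep-mat transect:
sulfate depleted to a low background within the upper few centimeters under
active mat versus a non-depleting profile outside it, volumetric rates
decaying exponentially with depth, a relative measurement precision of 3%
on concentrations, and clone libraries whose sulfate-reducer and
methane-cycler fractions co-vary with flux magnitude. Every generator is a
pure function of its parameters and seed.

Default physical constants (28 mM overlying sulfate, D_O = 5e-6 cm^2 s^-1,
porosity 0.8) are assumed seawater/soft-sediment values, not site
measurements, and are overridable.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .community import ActivityRow, RoleFractions, build_activity_summary, group_fractions
from .errors import ValidationError
from .fluxes import FluxResult, diffusive_flux_top, flag_saturation
from .profiles import DepthGrid, RateProfile, SoluteProfile
from .transport import TransportSystem, solve_forward

#: canonical phylogenetic groups and their ecological roles
DEFAULT_GROUP_ROLES = {
    "Eel-2": "SRB",
    "SEEP-SRB1": "SRB",
    "Desulfobacteraceae": "SRB",
    "Desulfobulbaceae": "SRB",
    "ANME-1b": "ANME",
    "ANME-2a": "ANME",
    "ANME-2c": "ANME",
    "Marine Group I": "other",
    "Alphaproteobacteria": "other",
    "Gammaproteobacteria": "other",
    "Bacteroidetes": "other",
    "Chloroflexi": "other",
    "DHVE8": "other",
    "MBG-D": "other",
}

#: sulfate background concentration (mM) used as the sub-mat bottom boundary
SULFATE_BACKGROUND_MM = 0.7


@dataclass(frozen=True)
class CoreScenario:
    """Parameters of one synthetic sediment core.

    rate_amplitude is the surface volumetric sulfate-reduction rate R0
    (nmol cm^-3 d^-1); rates decay as R0 * exp(-x / decay_length). The
    defaults are sized so that diffusion against the default transport
    system depletes a 28 mM sulfate profile to near-background within the
    upper ~5-8 cm, the sub-mat regime; 'outside' scenarios scale R0 down by
    outside_factor, leaving sulfate essentially non-depleting.
    """

    label: str  # mat | edge | outside
    C_OW: float = 28.0  # mM, overlying-water sulfate
    rate_amplitude: float = 2000.0  # R0, nmol cm^-3 d^-1
    decay_length_cm: float = 2.0
    noise_fraction: float = 0.03
    seed: int = 0
    outside_factor: float = 0.1

    def __post_init__(self):
        if self.label not in ("mat", "edge", "outside"):
            raise ValidationError("scenario label must be mat, edge, or outside")
        if self.decay_length_cm <= 0:
            raise ValidationError("decay length must be positive")
        if self.noise_fraction < 0:
            raise ValidationError("noise fraction must be >= 0")


def make_rate_profile(scn: CoreScenario, grid: DepthGrid) -> RateProfile:
    """Exponentially decaying volumetric rate R(x) = R0 * exp(-x/lambda)."""
    r0 = scn.rate_amplitude * (scn.outside_factor if scn.label == "outside" else 1.0)
    return RateProfile(grid, r0 * np.exp(-grid.x / scn.decay_length_cm))


def make_concentration_profile(
    scn: CoreScenario,
    sys: TransportSystem,
    rates: RateProfile,
    solute: str = "sulfate",
) -> SoluteProfile:
    """Forward steady-state solution with multiplicative measurement noise.

    Noise is Gaussian with standard deviation noise_fraction relative to the
    true value (the stated 3% replicate precision), truncated at zero; with
    noise_fraction 0 the forward solution is returned exactly.
    """
    truth = solve_forward(sys, rates).concentration
    if scn.noise_fraction > 0:
        rng = np.random.default_rng(scn.seed)
        truth = truth * (1.0 + scn.noise_fraction * rng.standard_normal(truth.shape))
        truth = np.maximum(truth, 0.0)
    return SoluteProfile(sys.grid, truth, solute=solute, precision_fraction=scn.noise_fraction)


def _largest_remainder(n: int, p: np.ndarray) -> np.ndarray:
    raw = n * p
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def make_community(
    scn: CoreScenario,
    n_clones: int,
    role_profile: dict[str, float],
    seed: int | None = None,
    concentration: float = 50.0,
    exact: bool = False,
    sample_id: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic clone-library count table and matching group map.

    role_profile maps phylogenetic group names to expected clone fractions
    (summing to 1). Group proportions are drawn from a Dirichlet centered on
    the profile (the concentration parameter controls spread), then clone
    counts multinomially. With ``exact=True`` the expected fractions are
    converted deterministically to counts (largest-remainder rounding) -
    the noise-free limit.
    """
    if n_clones < 1:
        raise ValidationError("n_clones must be >= 1")
    groups = list(role_profile)
    p = np.array([role_profile[g] for g in groups], dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError("role fractions must be non-negative and sum to 1")
    if exact:
        counts = _largest_remainder(n_clones, p)
    else:
        rng = np.random.default_rng(scn.seed if seed is None else seed)
        pos = p > 0
        props = np.zeros_like(p)
        props[pos] = rng.dirichlet(concentration * p[pos])
        counts = rng.multinomial(n_clones, props)
    sid = sample_id or scn.label
    count_df = pd.DataFrame({"sample_id": sid, "taxon_id": groups, "count": counts})
    count_df = count_df[count_df["count"] > 0].reset_index(drop=True)
    group_df = pd.DataFrame(
        {
            "taxon_id": groups,
            "group": groups,
            "role": [DEFAULT_GROUP_ROLES.get(g, "other") for g in groups],
        }
    )
    return count_df, group_df


def make_otu_abundances(
    true_richness: int,
    distribution: str = "log_series",
    sample_size: int = 100,
    seed: int = 0,
) -> list[int]:
    """Observed OTU size multiset from sampling a known richness pool.

    Individuals are drawn multinomially from `true_richness` OTUs whose
    relative abundances follow either a uniform or a log-series-shaped
    (p_i proportional to x**i / i, x = 0.97) distribution; only observed
    OTUs appear in the returned multiset.
    """
    if true_richness < 1 or sample_size < 1:
        raise ValidationError("true_richness and sample_size must be >= 1")
    if distribution == "uniform":
        p = np.full(true_richness, 1.0 / true_richness)
    elif distribution == "log_series":
        i = np.arange(1, true_richness + 1)
        w = 0.97**i / i
        p = w / w.sum()
    else:
        raise ValidationError("distribution must be 'uniform' or 'log_series'")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(sample_size, p)
    return sorted(int(c) for c in counts if c > 0)


# --- full transect ---------------------------------------------------------

#: designed surface clone-library compositions; SRB/ANME mass tracks flux
_SURFACE_PROFILES: dict[str, dict[str, dict[str, float]]] = {
    "mat": {
        "bacteria": {"Eel-2": 0.40, "SEEP-SRB1": 0.25, "Desulfobacteraceae": 0.10,
                     "Chloroflexi": 0.15, "Gammaproteobacteria": 0.10},
        "archaea": {"ANME-1b": 0.25, "ANME-2a": 0.30, "ANME-2c": 0.15,
                    "DHVE8": 0.20, "MBG-D": 0.10},
    },
    "edge": {
        "bacteria": {"Eel-2": 0.30, "SEEP-SRB1": 0.20, "Desulfobacteraceae": 0.10,
                     "Chloroflexi": 0.20, "Gammaproteobacteria": 0.20},
        "archaea": {"ANME-1b": 0.20, "ANME-2a": 0.25, "ANME-2c": 0.10,
                    "DHVE8": 0.25, "MBG-D": 0.20},
    },
    "outside": {
        "bacteria": {"Eel-2": 0.03, "SEEP-SRB1": 0.02, "Alphaproteobacteria": 0.40,
                     "Gammaproteobacteria": 0.30, "Bacteroidetes": 0.15, "Chloroflexi": 0.10},
        "archaea": {"ANME-2a": 0.05, "Marine Group I": 0.80, "MBG-D": 0.15},
    },
}
#: deep communities converge across the transect
_DEEP_PROFILE = {
    "bacteria": {"SEEP-SRB1": 0.35, "Desulfobacteraceae": 0.20, "Chloroflexi": 0.45},
    "archaea": {"ANME-1b": 0.25, "ANME-2a": 0.30, "MBG-D": 0.45},
}

_RATE_SCALE = {"mat": 1.0, "edge": 0.8, "outside": 1.0}
_METHANE_PRODUCTION_FACTOR = 0.03  # deep methane source relative to the sulfate sink


@dataclass(frozen=True)
class TransectCore:
    scenario: CoreScenario
    system: TransportSystem
    srr: RateProfile
    sulfate: SoluteProfile
    methane: SoluteProfile
    sulfate_flux: FluxResult
    methane_flux: FluxResult | None


@dataclass(frozen=True)
class Transect:
    cores: dict[str, TransectCore]
    rows: list[ActivityRow]
    bacterial: dict[str, RoleFractions]
    archaeal: dict[str, RoleFractions]


def simulate_transect(
    seed: int = 0,
    noise_fraction: float = 0.0,
    n_clones: int = 60,
    domain_bottom_cm: float = 20.0,
    dx_cm: float = 0.1,
) -> Transect:
    """Generate a full mat / edge / outside transect and its activity table.

    Sulfate is consumed by exponentially decaying rates scaled per core
    (mat > edge >> outside); mat and edge cores relax to the low sulfate
    background at the core bottom while the outside core stays near the
    overlying-water value. Methane is produced at depth, giving upward
    fluxes with the same ordering; deep methane under the mat and edge
    exceeds atmospheric saturation, so those deep fluxes are reported
    missing, as in a measured transect. Communities are drawn (or computed
    exactly in the noise-free limit) from role profiles whose SRB and ANME
    mass tracks the flux ordering at the surface and converges at depth.
    """
    grid = DepthGrid.uniform(domain_bottom_cm, dx_cm)
    exact = noise_fraction == 0.0
    rng = np.random.default_rng(seed)
    cores: dict[str, TransectCore] = {}
    rows: list[ActivityRow] = []
    bacterial: dict[str, RoleFractions] = {}
    archaeal: dict[str, RoleFractions] = {}
    libraries: dict[tuple[str, str, str], tuple[pd.DataFrame, pd.DataFrame]] = {}

    for label in ("mat", "edge", "outside"):
        scn = CoreScenario(
            label,
            rate_amplitude=2000.0 * _RATE_SCALE[label],
            noise_fraction=noise_fraction,
            seed=int(rng.integers(2**31 - 1)),
        )
        bottom = "zero_gradient" if label == "outside" else SULFATE_BACKGROUND_MM
        sys = TransportSystem(grid, overlying_concentration=scn.C_OW, bottom_boundary=bottom)
        srr = make_rate_profile(scn, grid)
        sulfate = make_concentration_profile(scn, sys, srr, solute="sulfate")

        # methane: produced at depth (negative consumption), near-zero at the top
        methane_sys = TransportSystem(grid, overlying_concentration=0.0)
        production = RateProfile(grid, -_METHANE_PRODUCTION_FACTOR * srr.rate[::-1])
        methane = make_concentration_profile(
            replace(scn, seed=scn.seed + 1), methane_sys, production, solute="methane"
        )

        phi = float(sys.porosity[0])
        Ds_cm2_s = float(sys.sediment_diffusivity[0]) / 86400.0
        sflux = diffusive_flux_top(sulfate, phi, Ds_cm2_s)
        top_saturated = bool(flag_saturation(methane)[:2].any())
        mflux = None if top_saturated else diffusive_flux_top(methane, phi, Ds_cm2_s)
        cores[label] = TransectCore(scn, sys, srr, sulfate, methane, sflux, mflux)

        for layer in ("surface", "deep"):
            designed = _SURFACE_PROFILES[label] if layer == "surface" else _DEEP_PROFILE
            for domain in ("bacteria", "archaea"):
                libraries[(layer, label, domain)] = make_community(
                    scn, n_clones, designed[domain],
                    seed=int(rng.integers(2**31 - 1)), exact=exact, sample_id=label,
                )

    for layer in ("surface", "deep"):
        fracs = {}
        for domain in ("bacteria", "archaea"):
            counts = pd.concat(
                [libraries[(layer, c, domain)][0] for c in cores], ignore_index=True
            )
            groups = pd.concat(
                [libraries[(layer, c, domain)][1] for c in cores], ignore_index=True
            ).drop_duplicates("taxon_id")
            fracs[domain] = group_fractions(counts, groups, domain)
        bacterial[layer] = fracs["bacteria"]
        archaeal[layer] = fracs["archaea"]

        if layer == "surface":
            sulfate_fluxes = {c: cores[c].sulfate_flux for c in cores}
            methane_fluxes: dict[str, FluxResult | None] = {c: cores[c].methane_flux for c in cores}
            # mRNA detected wherever seep metabolism is active; absent outside at the surface
            flags = {c: {"dsrAB": c != "outside", "mcrA": c != "outside"} for c in cores}
        else:
            sulfate_fluxes = {c: _deep_flux(cores[c].sulfate, cores[c].system) for c in cores}
            methane_fluxes = {
                c: (None if flag_saturation(cores[c].methane)[grid.x >= 12.0].any()
                    else _deep_flux(cores[c].methane, cores[c].system))
                for c in cores
            }
            flags = {c: {"dsrAB": True, "mcrA": True} for c in cores}
        rows.extend(
            build_activity_summary(
                fracs["bacteria"], fracs["archaea"], flags, sulfate_fluxes, methane_fluxes, layer
            )
        )
    return Transect(cores, rows, bacterial, archaeal)


def _deep_flux(profile: SoluteProfile, sys: TransportSystem) -> FluxResult:
    """Diffusive flux across the 12-15 cm interval midpoints."""
    x = profile.grid.x
    i = int(np.searchsorted(x, 12.0))
    j = int(np.searchsorted(x, 15.0))
    sub = SoluteProfile(
        DepthGrid(x[[i, j]]), profile.concentration[[i, j]], solute=profile.solute
    )
    phi = float(sys.porosity[0])
    return diffusive_flux_top(sub, phi, float(sys.sediment_diffusivity[0]) / 86400.0)
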