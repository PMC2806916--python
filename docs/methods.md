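# Methods

## Reaction-transport model

The transport module solves the 1-D steady-state balance for a porewater
solute C(x) (mM, with x in cm below the sediment–water interface, positive
down):

    d/dx( φ D_s dC/dx ) − d(φ ω C)/dx + φ α (C_ow − C) − φ R = 0

- **Diffusion.** D_s is the tortuosity-corrected sediment diffusivity,
  D_s = D_O / (1 − ln φ²), from the molecular diffusivity D_O (cm² s⁻¹,
  default 5×10⁻⁶, a sulfate-at-cold-seawater value). The correction is the
  standard porewater practice and can be disabled (`tortuosity=False`), in
  which case D_s = D_O.
- **Burial.** ω is the sedimentation rate, accepted in cm kyr⁻¹ and
  converted with 365.25 d yr⁻¹; the advective term uses a constant φω
  product (steady compaction), evaluated with the surface porosity. An
  optional upward pore-fluid velocity (off by default) subtracts from ω.
- **Bioirrigation.** A nonlocal exchange α(x) (d⁻¹, ≥0) toward the
  overlying-water concentration C_ow.
- **Reaction.** R(x) is the volumetric consumption rate of the modeled
  solute in nmol cm⁻³ d⁻¹; production (e.g. methanogenesis for methane)
  enters with a negative sign, so one solver serves both solutes.

Internal units are cm, days, and mM (≡ µmol cm⁻³); all conversions happen
at the module boundary.

### Discretization and boundary conditions

Second-order central finite differences on the node grid (uniform spacing
by default, `dx = 0.1 cm`) give a tridiagonal system solved with a banded
LU factorization. The top boundary is Dirichlet at C_ow. The bottom is
configurable: a fixed value, or the default zero-gradient condition
implemented with a mirrored ghost node, which preserves second-order
accuracy — the test suite verifies an observed convergence order ≈ 2
against a non-polynomial closed form. Zero gradient is the weakest
defensible assumption for the bottom of a push core; the fixed-value option
suits cores that relax to a known background.

Negative solution values are reported, not clipped: they are the diagnostic
that an imposed rate exceeds what transport can supply.

### Inverse modeling

The steady state is affine in R, so fitting piecewise-constant rates over
n contiguous layers is linear least squares on precomputed unit-rate
response profiles (one forward solve per layer plus one for the
zero-rate base state). Rank deficiency of the response design raises an
estimation error rather than returning arbitrary coefficients; fitted
rates may be negative (net production). The noise-robustness test uses
layer rates (40/15/5 nmol cm⁻³ d⁻¹ over 10 cm layers) chosen so the true
profile stays positive everywhere — i.e. the regime measured profiles
actually occupy — and recovers medians within a few percent under the 3 %
measurement precision.

### Penetration depth

The shallowest depth where the linearly interpolated concentration falls to
a threshold (default 0.7 mM, the sulfate background below the depletion
zone). A profile that never reaches the threshold returns a beyond-domain
marker carrying the domain bottom, which downstream comparisons treat as
"deeper than the domain".

## Fluxes and budgets

Diffusive flux across the first two depths of a profile:
J = φ D_s ΔC/Δx, converted to mmol m⁻² d⁻¹, with **positive = upward, out
of the sediment** — so sulfate transported into the sediment carries a
negative flux and summaries plot its absolute value. The gradient uses
interval midpoints when profiles come from sectioned cores. Porosity enters
the flux by default and is toggleable, since reported fluxes in the
literature are not always porosity-corrected.

Depth-integrated rates use the trapezoid rule
(nmol cm⁻³ d⁻¹ · cm = 0.01 mmol m⁻² d⁻¹) over a window defaulting to the
upper 25 cm; gaps outside the measured profile integrate as zero and
replicate values at the same depth are averaged upstream. The flux/rate
consistency check flags a pairing as agreeing when |flux|/rate lies within
a factor of 3 (both-zero is agreement with ratio 1 by convention); the
factor is configurable because the underlying judgment is qualitative.

mRNA persistence time is depth offset ÷ sedimentation rate × 1000 (years),
reported exact and floored; methane readings above 1.2 mM — the 1 atm
outgassing ceiling — are flagged as lower bounds rather than corrected,
since in-situ pressure correction is out of scope.

## Isotopes

δ¹³C = (R_sample/R_standard − 1)·1000 with the conventional VPDB ratio
0.0112372 (overridable). The upcore trend call is the sign of the
least-squares slope of δ vs. depth with a 1 ‰ minimum change over the
profile span — a deliberate slope-sign heuristic, not a hypothesis test,
because the scientific argument is from profile shape. Three measured
depths are required; with four or more, a call that flips when the single
shallowest point is dropped is refused as indeterminate, since a lone
surface excursion can reflect aerobic oxidation at the interface.

## Diversity

p-distance excludes sites with a gap or IUPAC ambiguity in either sequence
from numerator and denominator; a pair with no comparable sites is an
error. OTU clustering is agglomerative furthest-neighbor (complete)
linkage cut at the distance threshold (98 % similarity ↔ 0.02), merging in
ascending linkage order with lexicographic tie-breaks; complete linkage
guarantees every OTU's maximum intra-cluster distance is within the
threshold. The implementation is the naive O(n³) agglomeration — clone
libraries are tens to hundreds of sequences — and the test suite checks it
against scipy's independent complete-linkage implementation on random
matrices.

Chao1 uses the bias-corrected form S_obs + n₁(n₁−1)/(2(n₂+1)), whose
correction vanishes when n₁ ≤ 1 and which never falls below S_obs. The
library-size QC computes |size − mean|/size per library (each library's own
size as denominator) and flags deviations ≥ 20 %; QC is intended per domain
(bacteria vs. archaea) since the two amplicon sets target different library
sizes.

## Community summaries

Role percentages come solely from a user-supplied taxon → group → role map
(roles: SRB, ANME, other); no taxonomy is inferred. The activity summary
joins role percentages with marker-gene detections (encoded 100/0), the
absolute sulfate flux, and methane flux × 10 — the encodings of the
standard transect comparison figure — carrying missing methane fluxes with
an explicit reason (saturation-censored profiles). Concordance between
flux ordering and community fractions is an exhaustive pair enumeration
(Kendall-style concordant-pair fraction) with ties reported and excluded:
with three cores per layer a fitted correlation would be meaningless.

## Synthetic data

Generators are pure functions of (parameters, seed):

- **Rates**: R(x) = R₀ e^(−x/λ). Defaults R₀ = 2000 nmol cm⁻³ d⁻¹, λ = 2 cm
  are sized so that, against the default transport system, sulfate depletes
  to near-background within the upper ~5–8 cm — the sub-mat regime; the
  "outside" scenario scales R₀ by 0.1 and leaves sulfate essentially
  non-depleting.
- **Concentrations**: forward solution × multiplicative Gaussian noise of
  relative sd `noise_fraction` (default 0.03, the stated replicate
  precision), truncated at zero.
- **Communities**: group proportions from a Dirichlet centered on designed
  fractions (concentration 50), clone counts multinomial; the noise-free
  limit uses deterministic largest-remainder rounding.
- **OTU pools**: multinomial draws from uniform or log-series-shaped
  abundances, supporting the Chao1 property tests.
- **Transect**: mat/edge/outside cores with effective rate amplitudes in
  the ratio 1 : 0.8 : 0.1 (the outside factor applied to the shared
  amplitude), with surface
  communities whose SRB/ANME fractions track the flux ordering and deep
  communities that converge; deep methane under mat and edge exceeds the
  1.2 mM ceiling and is saturation-censored. Default 20 cm domain,
  60 clones per library.

What the generators do **not** emulate: sequencing error and chimeras,
primer bias, compaction gradients in porosity, transient (non-steady)
chemistry, or in-situ pressure effects on gas solubility. Passing tests
therefore demonstrate the correctness and internal consistency of the
analysis chain under its stated assumptions, not the field validity of
those assumptions.

## Numerical choices and limitations

- Intervals are half-open [top, bottom); point depths are interval
  midpoints.
- Equality at a flag threshold (methane 1.2 mM) does not flag; QC deviation
  exactly 0.20 does flag (strict "<" pass rule).
- The solver is steady-state only; no multi-solute kinetics or
  chloride-based advection estimation.
- Forward/inverse problem sizes in tests (≤ 401 nodes, ≤ 100 noise
  replicates) are the package's chosen default scales; the linear-algebra
  core is O(n) per solve and scales to much finer grids.
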