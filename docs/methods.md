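# Methods

This note documents the models implemented in `hydrotrap`, the choices
made where the underlying physics or published description left the
design open, and what the synthetic-data tests do and do not establish.

## Physical picture and units

A micropipette held a few micrometres above a supported lipid bilayer
(SLB) draws liquid inward; the wall shear stress σ_hydro(r) drags
membrane-anchored molecules toward the pipette axis with force
F = A_hydro · σ_hydro, where A_hydro is the molecule's effective
hydrodynamic area. At steady state the drag balances the chemical
potential gradient, ∂μ/∂r = F, so integrating along the radius gives

    μ(c) = μ(c0) + ∫₀^ε A_hydro(c) dε,      ε(r) = ∫_r^∞ σ_hydro dr′,

with ε the trap-energy density (J/m²): the work per unit hydrodynamic
area to bring a molecule from infinity to radius r. All energies are in
k_BT (k_BT ≡ 1 internally; the single Joule-valued constant,
k_BT = 4.11·10⁻²¹ J at room temperature, lives in `hydrotrap.units` and
is used only to convert ε·area products into k_BT). Lengths are nm for
molecules, µm for images; surface densities are molecules/µm².
σ_hydro is stored as the magnitude of the inward stress, so ε ≥ 0 and
decreases outward; the sign convention absorbs the minus sign of the
defining integral.

## Hard-disk thermodynamics (`thermo`)

The reference interaction model is the 2D hard-disk fluid with the
virial equation of state truncated after the fourth coefficient:

    μ(Φ) = μ0 + ln Φ + 2B₂Φ + (3/2)B₃Φ² + (4/3)B₄Φ³,
    B₂ = 2, B₃ = 3.128, B₄ = 4.258,   Φ = c·πa².

The truncation is part of the model, not an approximation we control;
no higher terms are added. μ0 is fixed to 0 because only differences in
μ are ever used. The truncated series is accurate to a few percent up
to Φ ≈ 0.5 and the generator warns beyond a configurable coverage cap
(default 0.5) where the virial form should not be trusted.

Radius fitting minimises least-squares residuals of μ^ex with a
log-radius parameterisation; residuals are relative by default
(scaled by max(|μ^ex|, 0.05 k_BT)) with optional weights, and can be
switched to absolute. When the ambient density c0 is supplied, model
curves are referenced to it (μ^ex(c) − μ^ex(c0)), because the
measurement chain yields the excess chemical potential *relative to the
untrapped baseline* — at ε = 0 the measured μ^ex is exactly zero by
construction. Boundary-pinned or non-convergent fits are reported as
failures, never silently returned.

The glycosylation map between normalized projected area A_p and
hard-disk area,

    A_hd = (p₁(A_p−1)² + p₂(A_p−1) + 1) / (p₁(A_p−1)²/9.82 + 1),

uses p₁ = 0.66, p₂ = 0.95 and plateau 9.82 = ((0.15+0.32)/0.15)², the
normalized projected area of a disk with radius equal to protein radius
plus sugar length. When refitting, the plateau is held fixed: it is a
geometric quantity, not a free parameter. As a purely empirical form
the curve mildly overshoots the plateau if extrapolated to projected
areas far beyond it; the physical domain ends at A_p = 9.82 (a
projected area cannot exceed the plateau disk) and the function is
monotone and bounded there.

## Hydrodynamic area model (`hydro`)

The zero-coverage area of a cylinder of radius a and height h_c uses
the empirical expression

    A_hydro(0) = (0.65(h_c/a)² + 5.0(h_c/a) + 1)·πa².

Its inversion for h_c is the closed-form positive root of the quadratic
in h_c/a; the round trip is exact to 10⁻¹⁰ relative and reproduces all
four published effective heights at the table's rounding.

Coverage shielding uses g(Φ) = (1−Φ)^ν with ν configurable (default 1);
the published coverage dependence is not printed, so only the contract
(g(0) = 1, monotone non-increasing, 0 < g ≤ 1) is guaranteed, and ν = 0
disables shielding. The same knob is exposed everywhere the area enters.

The finite-element flow solver behind the published ε profiles is out
of scope. In its place a parametric stress kernel generates physically
shaped profiles:

    σ(r) = σ₀·(r/w)·exp(−r²/2w²),   w = tip radius + gap,
    σ₀ = α·|Δp|·tip/w,

which vanishes at the stagnation point, peaks near the pipette rim and
decays outward, with closed-form ε(r) = σ₀·w·exp(−r²/2w²). The
amplitude is linear in the applied pressure (Stokes flow), and the
default α = 0.01 puts peak trap energies near 10⁻⁴ J/m² for the
experimental pressures (−3.0/−9.7/−19.4 kPa); scenario presets pin the
−9.7 kPa profile to exactly 10⁻⁴ J/m² at the centre. The kernel exists
to exercise the analysis, not to reproduce any specific flow field;
users with real solver output supply tabulated σ(r) or ε(r) CSVs, which
are integrated with the trapezoid rule on the supplied grid without
resampling (a truncation warning fires if σ has not decayed to 10⁻³ of
its peak at the outer edge).

## Monte Carlo (`mc`)

Molecules are rigid chains of spheres, one sphere grafted to a hard
wall at z = 0 (its centre at one radius above the wall), with periodic
boundaries in x and y. Moves are single-molecule translations along the
wall and rigid rotations about the graft-sphere centre, accepted by the
Metropolis rule; amplitudes are auto-tuned to 30–50% acceptance during
equilibration (default the leading 20% of steps) and then frozen.
Initial states come from random sequential insertion with a square
lattice fallback; an unplaceable density reports the achievable
capacity. Runs are bit-reproducible for a given seed, and the
incrementally tracked energy is checked against a fresh recomputation
(agreement to 10⁻⁸ relative in tests).

Pair interactions are the cut-and-shifted repulsive Lennard-Jones (WCA)
form, zero at and beyond 2^{1/6}σ_ij with σ_ij the sum of the two
radii. The repulsion strength ε_LJ is a model parameter: the soft disk
behaves like a hard disk of diameter d_eff(ε_LJ), with
d_eff from matching the 2D second virial coefficient. The convention
adopted throughout compares soft-disk simulations to hard-disk theory
after multiplying coverages by 1.075², i.e. the effective hard-disk
radius is 7.5% larger than nominal; we therefore set ε_LJ = 8.244 k_BT,
the value whose B2-matched d_eff is exactly 1.075σ (at ε_LJ = 1 k_BT
the effective diameter would be only 1.016σ, inconsistent with that
correction factor). Squat single-sphere molecules then reproduce the
virial μ^ex within 5% up to Φ ≈ 0.2, which is the empirical pin for the
choice. Overlapping configurations are handled with a finite energy cap
(10³ k_BT) so trial states are rejected rather than overflowing.

Tilt restraint: u = k_f·(z − L_max)², k_f in k_BT/Å², acting on the
altitude of the top sphere's centre, with L_max its altitude when
upright (so the restraint is zero for the upright molecule). k_f = 0
leaves free rotation (±90°, bounded by the wall); `rigid=True`
implements the k_f → ∞ limit without wasted moves. The mapping between
k_f and an allowed tilt angle depends on the chain length;
`calibrate_restraint` computes k_f for a target tilt quantile under the
single-molecule distribution p(θ) ∝ sinθ·e^{−u(θ)}, and
`tilt_distribution` exposes the distribution itself. The flexibility
study uses the three published spring constants k_f = 1, 5, 50 k_BT/Å²
(labelled ±50°, ±10°, 0°) plus k_f = 0 (±90°).

Widom insertion: μ^ex = −ln⟨e^{−ΔU}⟩ over ghost molecules placed
uniformly on the wall with orientations drawn from the isolated
molecule's Boltzmann distribution (restraint × sinθ measure × wall).
With this insertion measure the reference state is the isolated grafted
molecule, so μ^ex → 0 exactly as Φ → 0. Standard errors divide the
sample variance by an effective sample size from the integrated
autocorrelation time of the per-sample means (validated against
between-seed scatter). A run whose every insertion overlapped reports a
flagged lower bound instead of a number.

Coverage sweeps hold the molecule count fixed (default 40–48) and scale
the periodic box to realise each coverage, which keeps statistics
comparable across the grid; the printed 2×2×2 nm box is the default
`SimulationBox` for the 0.1 nm-sphere systems. Production runs default
to 10⁵ steps per point (the published 10⁶ scaled down, with the reduced
precision the stochastic tests state); the run length is config.

The coverage where μ^ex(Φ) crosses 1 k_BT (linear interpolation between
bracketing points) defines the molecule's effective hard-disk area:
A_eff ∝ 1/Φ*(1 k_BT). The flexibility amplification reported for a
rotating vs rigid rod is the ratio Φ*_rigid/Φ*_flexible — the factor by
which the molecule's effective footprint grows. For the three-sphere
3:1 rod this evaluates to ≈ 2.3 (free rotation), ≈ 1.9 (k_f = 1) and
≈ 1.6 (k_f = 5), matching the published 2.3/1.7/1.4 progression; a
square-root (linear-width) convention cannot reach the published free-
rotation factor for any rod of this aspect ratio (the fully flat Mayer
bound is ≈ 2.1), which identifies the published factors as area ratios.

Glyco systems: protein = three stacked 0.3 nm spheres; each sugar = two
connected 0.16 nm spheres extending horizontally from a protein
sphere's surface, all sugars in one molecular plane by default
(attachment sphere and azimuth are configurable). Projected areas are
circle-union areas (shapely) of the upright molecule's sphere
projections, normalized to the sugar-free protein; hard-disk areas come
from 1 k_BT coverage ratios against the sugar-free molecule.

## Measurement pipeline (`pipeline`)

Trap centre: intensity-weighted centroid of top-quantile pixels,
refined iteratively in a circular window (symmetric about the estimate,
hence free of threshold-mask bias); featureless images are rejected.
Radial averaging uses one-pixel annuli by default, reported out to the
largest fully contained annulus, empty bins dropped. Intensity →
density is linear, (I − background)·factor, calibrated either by a
single-molecule intensity or by anchoring the far field to a known
ambient density; negative background-subtracted values clip to zero
with a warning.

The interaction curve pairs c(r) with ε(r), interpolating ε onto the
concentration bins (those carry the measurement statistics). The
baseline c0 is the mean concentration where ε < 2% of its peak. The
low-coverage slope of ln c vs ε gives A_hydro(0)·k_BT⁻¹; the coverage
cutoff defaults to Φ ≤ 0.05 under a provisional radius and is reported
with the result. The cutoff trades bias for noise: finite coverage
biases the slope low (the interacting term steals part of the
gradient), about −1% at Φ ≤ 0.01 and −5% at Φ ≤ 0.05 for a 3.2 nm disk
at ε_max = 10⁻⁴ J/m²; tests therefore use the stricter cutoffs and the
default remains the conventional 0.05. A statistically flat curve is
flagged, not returned as an area.

μ(c) integrates A_hydro(c(ε)) dε by the trapezoid rule; μ^ex subtracts
ln(c/c0) and is zero at the baseline by construction (equivalently: it
is measured relative to the ambient state — model fits must be
referenced the same way, which `c0=` arguments do). Non-monotone c(ε)
beyond a 2% tolerance triggers isotonic pre-smoothing with a warning;
the raw values are always returned alongside.

Model ranking fits each candidate (hard disk, or a simulated μ^ex(Φ)
curve library entry) with one scale parameter — the cross-section
radius mapping c to Φ — under the same residual convention, and ranks
by residual norm. A library curve that does not reach the data's
coverage range is skipped with a reason rather than extrapolated.

Two-species model: the coupled steady state integrates
dμ_i/dε = A_i(c₁,c₂) from the far field with a binary hard-disk
mixture chemical potential — full virial series in each species' own
coverage plus a second-virial cross term 2·B₂^cross·ρ_j with
B₂^cross = π(a₁+a₂)²/2, consistent with B₂ = 2 of the one-component
series. Flow shielding of the smaller species by the larger one's local
coverage (g(Φ_large), exponent configurable) is the mechanism that
produces the ring-shaped segregation; optional total-coverage shielding
applies to both. The mixture treatment is second-virial-level in the
cross term and is deliberately labelled qualitative: tests exercise
orderings and limits (reduction to one species, symmetry, far-field
baselines, ring ordering), not quantitative profiles.

## Synthetic data (`synthdata`)

`forward_steady_state` solves (1/c + dμ^ex/dc)·dc/dε = A_hydro(c)/k_BT
up the trap-energy axis (LSODA, rtol 10⁻⁹) and maps the solution onto
any radial grid; for ideal molecules with constant area it matches
c = c0·e^{Aε/k_BT} to 10⁻⁶. Supported interaction models: hard disk,
ideal, and a μ^ex linear in coverage (the shape free-rod simulations
produce; the CD45-like preset uses slope 1/0.078, i.e. unit μ^ex at the
free rod's 1 k_BT coverage).

`render_image` draws pixel means background + c·(intensity per
molecule), Poisson counting noise plus Gaussian read noise (σ = 2
counts), clipped to 16 bits with a saturation warning — choose the
intensity per molecule so the trap centre stays inside the dynamic
range. No optical blur by default (trap features span many pixels); a
Gaussian PSF knob exists for robustness testing. Rendering is
deterministic per seed, and ground-truth metadata serialises to JSON so
regeneration is bit-identical.

Presets: SA (a = 2.8 nm, h_c = 5 nm, hard disk 3.2 nm), CD2 (1.5, 7.5,
disk 5.3 nm), CD4 (1.5, 11, disk 3.7 nm), CD45-rotating-rod (linear
μ^ex, rod radius 3.8 nm), each with ambient densities in the
experimental 100–1000 µm⁻² range (300, or 150 for the large molecule)
and the −9.7 kPa flow profile peaking at 10⁻⁴ J/m². The preset disk
radii and areas are the published *measured* values; they parameterise
synthetic scenarios and are not re-derived by this package (the
experimental curves and flow fields are unreleased).

## What the synthetic tests do and do not show

The generator emulates radially symmetric steady-state accumulation
with camera noise. It shares its μ-models and shielding family with the
analysis — round trips therefore validate the *inference machinery*
(geometry, calibration, integration, fitting and their biases), not the
physical truth of those models. It does not emulate photobleaching,
crystallization, drift, time-dependent accumulation, optical blur (by
default), or deviations of real flow fields from the parametric kernel.
Parameter-recovery results (areas and radii within 5% at ~1% profile
noise) should be read with that scope in mind.

## Problem sizes and numerical settings

Stochastic tests and the acceptance script run 10⁵-step MC runs with
40–48 molecules, 20 ghost insertions every 40–50 steps, and 2–3 seeds —
sizes chosen so the whole suite runs on one CPU in minutes while
keeping Widom standard errors near 0.01–0.02 k_BT. Tolerances follow:
virial agreement 5%, flexibility factors 15%, seed-to-seed agreement
3 combined standard errors. Deterministic numerics: trapezoid
quadrature on supplied grids, LSODA with rtol 10⁻⁹ for steady states,
brentq for scalar roots, least-squares fits in log-radius space.

## Known limitations

* The virial truncation degrades above Φ ≈ 0.5; the generator caps
  coverage there and the two-species mixture is cross-B₂ only.
* A_hydro(c) beyond its zero-coverage value is a one-parameter
  shielding family, not a hydrodynamic calculation.
* The low-coverage slope estimator has a known negative bias growing
  with the coverage cutoff (quantified above); choose the cutoff to
  taste and read the reported value with it.
* Rotation moves pivot about the graft-sphere centre; molecules whose
  graft sphere should roll on the wall are not modelled.
* The restraint acts on the top sphere only, as published; long chains
  with off-axis top spheres use the on-axis approximation in the
  insertion-orientation sampler.
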