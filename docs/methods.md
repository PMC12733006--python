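# Methods

This note records the models, conventions, numerical choices and known
limitations behind `spc_rheoflow`. It documents what the code computes;
every number quoted here is produced by the test suite or the example
scripts, not asserted independently.

## Oscillatory-shear decomposition

For a strain-controlled oscillation γ(t) = γ₀ sin ωt, a material with odd
(strain-reversal) symmetry responds with odd stress harmonics only:

σ(t) = γ₀ Σₙ odd [G′ₙ sin nωt + G″ₙ cos nωt]
     = γ₀ Σ eₙ Tₙ(γ/γ₀) + γ₀ω Σ vₙ Tₙ(γ̇/γ₀ω),

where Tₙ are Chebyshev polynomials of the first kind and the two bases are
related by eₙ = (−1)^((n−1)/2) G′ₙ, vₙ = G″ₙ/ω (from Tₙ(sin θ) =
(−1)^((n−1)/2) sin nθ and Tₙ(cos θ) = cos nθ). `decompose` evaluates the
harmonics by FFT over the integer-cycle window.

**Phase referencing.** Instruments do not guarantee that sampling starts
at strain zero. The strain channel is therefore fit to γ₀ sin(ωt+φ) via
its fundamental Fourier component and every stress harmonic is rotated by
−nφ before reporting. This makes the decomposition invariant to the
sampling start (verified to 1e−8 in the tests by rolling waveforms).

**Truncation.** Default `max_order` 9; harmonics below 1e−6 of the
first-harmonic magnitude are reported as zero. The higher-order terms
enter the intracycle measures with weights up to n = 9, so letting noise
populate them would amplify error in S and T; the residual RMS of the
un-modelled stress (including all even-harmonic power, which odd symmetry
forbids physically and which is therefore a data-quality diagnostic) is
reported alongside.

**Intracycle measures.** G′_M (tangent modulus at γ = 0), G′_L (secant
modulus at γ = ±γ₀), η′_M, η′_L, and the ratios S = (G′_L−G′_M)/G′_L,
T = (η′_L−η′_M)/η′_L are evaluated from the retained coefficient series.
A slope-based evaluator (`slope_measures`, numerical tangent/secant on the
reconstructed loop) cross-checks the series forms; disagreement beyond
~1% flags an under-resolved harmonic set. Ratios with vanishing
denominators are NaN, not errors.

**Loop areas.** The elastic Lissajous–Bowditch loop (stress vs strain)
encloses the energy dissipated per cycle and unit volume, πγ₀²G″₁ — only
the first viscous harmonic dissipates. Symmetrically, the viscous loop
(stress vs rate/ω) encloses πγ₀²e₁ and is independent of the viscous
coefficients; both identities are asserted numerically (shoelace rule,
0.1%).

## Linear-regime analysis

Power-law fits of G′, G″ against ω are least squares in log–log space.
Crossovers are located by log-log linear interpolation of ln G′ − ln G″;
absence of a sign change is a value ("no crossover", the viscous-dominated
paste case), not an error. Interpolations elsewhere are linear in
log-strain/log-frequency versus linear modulus, the stable choice across
decades.

**Plateau and critical strain.** The linear-viscoelastic plateau is the
median of G′ over the longest initial window in which G′ stays within 1%
of its first point. A point-to-point change criterion was rejected: a
modulus decaying slowly enough never violates it, and the window then
creeps arbitrarily far into the decay. The median makes the estimate
insensitive to the decay tail entering the window. γ_cr is the
interpolated strain where G′ = 0.95 × plateau; by that convention
G′(γ_cr) equals the threshold exactly. Limitation: with a noisy first
point the 1%-band anchor degrades; sweeps should start well inside the
linear regime.

**Cohesive energy density.** E_c = ½γ_cr²G′_cr. The packaged
characterization tables only reproduce their printed E_c values when γ_cr
is inserted as the *percent number* (0.23, not 0.0023); this dimensional
shortcut is the table convention and the package default, with the
SI-consistent fraction form available via a flag (values then differ by
1e4). The printed E_c are replicate means of per-replicate products, so
the product of printed means matches them only to a few percent; tests use
a 5% band.

## Constitutive models

**Model A (generalized Newtonian).** η(γ̇,T) = K(T)γ̇^(n(T)−1) with
Arrhenius K(T) = K₀ exp[(E_a/R)(1/T − 1/T_ref)] and n(T) = n₀ +
α_n(T−T_ref), n clamped to (0, 2). The shear rate is floored at 1e−4 s⁻¹
to regularize the n < 1 singularity at zero shear. Arrhenius evaluations
satisfy the reference-shift group property (re-deriving K₀ at another
T_ref leaves K(T) unchanged).

**Model B (exponential PTT).** Single mode, no solvent contribution:
f(τ)τ + λ(T)τ^∇ = 2η₀(T)D, f = exp[(ελ/η₀) tr τ], with Arrhenius shifts
on η₀ and λ. In steady simple shear τ_yy = τ_zz = 0, tr τ = τ_xx, and the
system reduces to the scalar equation u e^{2u} = 2ελ²γ̇² with
u = ελτ_xx/η₀, giving τ_xy = η₀γ̇e^{−u} and N₁ = τ_xx. The solver uses
damped Newton on this equation; the Lambert-W closed form and transient
integration of the tensor ODE serve as independent oracles in the tests.
Two useful exact corollaries: the shear stress is monotone in γ̇
(asymptotically η₀√(ln γ̇)-like, so no constitutive instability), and the
inverse viscometric map is explicit — u = 2ελ²τ_xy²/η₀², γ̇ =
(τ_xy/η₀)e^{u} — which the flow solver exploits.

LAOS cycles integrate the (τ_xx, τ_xy) ODE system per cycle (LSODA,
rtol 1e−10) until the cycle-to-cycle stress RMS change falls below 1e−6;
with λω = O(1) the transient dies in a few cycles.

**Parameter extraction.** λ = 1/ω_c from the crossover. η₀ is the
low-frequency limit of G″/ω, estimated by least squares of G″ against the
single-mode basis ω/(1+(λω)²) over the lowest decade — the basis reduces
to ω as ω→0, so the coefficient is the zero-shear slope, while the
Maxwell-consistent curvature keeps it unbiased when the lowest decade
already bends; the alternative reading (plateau of G′(1+1/(λω)²) times λ)
is reported alongside and coincides for single-mode data. ε is found from
the measured e₃/e₁ at a reference amplitude by simulating LAOS cycles:
e₃/e₁(ε) is *not* monotone (intracycle softening at small ε turns to
stiffening at large ε), so the search scans a log-dense ε grid in [0, 1]
for the first sign change and refines with brentq (xtol 1e−4), returning
the smallest — weak-nonlinearity — root. A measured ratio can also sit at
the attainable extremum of the curve; a bounded minimization fallback
accepts such near-tangent matches (within 10% of the target or 1e−4
absolute). ε > 1 is treated as unphysical for melts. The functional route
from (e₃/e₁, v₃/v₁) to ε is this package's construction and is labelled
as such in reports. With only reference-state data available, E_η and
E_λ default to 0 (thermorheologically constant); when two temperatures
are available they are fitted equal (thermorheological simplicity).

Self-recovery (parameters extracted from data the model itself generated)
reproduces λ and η₀ to better than 0.5% and ε to better than 2%.

## Cooling-die solver

Geometry: rectangular die, default 20 mm × 10 mm × 500 mm, wall
temperature zones 100/50/10 °C with boundaries at 100 and 350 mm from the
die entry; melt enters at 100 °C; outlet at zero gauge pressure. Default
inlet flow is piston-derived (89.8 mm piston at 1 mm/s → 6.33 mL/s).

**Reduction.** The full 3-D problem is replaced by axial marching with a
locally fully developed cross-section (a Graetz-type reduction, valid for
slow, high-viscosity laminar flow where axial diffusion is negligible —
Péclet numbers here are O(10²)):

1. At each station the plane-channel profile over the 10 mm gap is solved
   for the local pressure gradient: τ(y) = Gy, the constitutive law is
   inverted pointwise for γ̇(τ, T(y)) (closed form for both models), and
   G is found by brentq so the discrete trapezoid flow rate matches the
   imposed rate exactly (this makes mass conservation exact by
   construction, which the tests verify from the stored profiles). The
   finite width enters through the Newtonian rectangular-duct shape
   factor applied to the pressure gradient — exact for Newtonian flow, an
   approximation otherwise.
2. The energy equation ρc_p u ∂T/∂z = ∂/∂y(k ∂T/∂y) + τγ̇ advances by an
   implicit (backward-Euler) step with lagged c_p(T), k(T), symmetry at
   the mid-gap and the zone wall temperature as Dirichlet condition.
   Viscous dissipation is on by default and toggleable. The discrete wall
   flux and dissipation are accumulated with finite-volume-consistent
   weights, so the global energy balance (enthalpy deficit = wall loss +
   dissipation) closes to machine precision on fixed-profile cases and
   within 1% generally.
3. Pressure integrates the corrected gradients backwards from the
   zero-gauge outlet.

Default resolution is 24 transverse cells over the half gap × 250 axial
steps; `mesh_independence` reports the relative pressure-drop change
under refinement against a 2% criterion (0.1% typical at default
resolution). The Newtonian solution matches the exact duct series to
0.1%, and the power-law slab profile matches its closed form to better
than 1%.

**Flow calibration.** The piston-derived inlet flow and the reported melt
cooling are mutually inconsistent: at 6.33 mL/s the residence time
(~16 s) is far below the gap diffusion time (~190 s), so the bulk melt
could not cool as observed. The solver therefore offers a one-scalar
calibration that rescales the inlet flow until the mixing-cup temperature
at the end of the mid zone matches a target (86 °C by default, the melt
temperature the process reports reaching through the mid-section); both
the uncalibrated and calibrated modes are available and the calibration
factor is reported. After calibration the zone means, outlet temperature
and pressure drop are genuine predictions. For the oil-free sample the
calibrated model predicts an outlet bulk temperature of ≈73.6 °C against
a reported 70.27 ± 1.55 °C; no single flow scalar can reproduce the full
reported profile (99 °C inlet region / 86 °C mid / 70.3 °C outlet) under
fixed 100/50/10 °C wall temperatures — the reported profile decays more
slowly mid-die and faster at the end than any advection–conduction
solution with these boundary conditions permits — and the acceptance test
records this residual miss rather than widening the band.

**Bulk temperatures** are velocity-weighted (mixing-cup) means; zone
summaries average them over each zone's stations.

**RMSE validation** is √(Σ(pred−obs)²/N) per quantity (pressure Pa,
temperature °C, velocity m/s) on user-supplied paired series; where
measured probe positions are unknown, pairing is the caller's choice.

## Synthetic data

Generators define the study conditions for all tests: waveforms default to
8 cycles × 256 samples/cycle (integer-cycle windows avoid spectral
leakage; no start-up transient is emulated since waveforms are
constructed at steady state), frequency sweeps cover 0.1–100 rad/s
(extended to 0.01 rad/s where a λ = 1 s crossover must be bracketed
comfortably), amplitude sweeps 0.1–1000% at 1 rad/s. Noise is additive
Gaussian on stress waveforms and multiplicative lognormal on sweep moduli
(instrument error scales with modulus amplitude). All generators are
seeded and bit-reproducible.

What the generators do *not* emulate — instrument inertia, gap loading,
transients, wall slip, sample drying, thermal gradients in the sample —
bounds what the tests show: they validate the analysis and modeling chain
on idealized signals with known truth, not the package's robustness to
instrument artifacts.

## Temperature-polynomial convention

The packaged c_p(T) and k(T) polynomials are evaluated with T in °C,
which reproduces the expected magnitudes (c_p ≈ 3613 J/(kg·K) at 20 °C,
k ≈ 0.52 W/(m·K)) over the process range; the convention is a documented
default of the material table, not hard-coded physics.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen for convergence at
the tolerances asserted: LAOS round trips at 2048 samples, Monte-Carlo
fit studies at 200–300 seeds, die solves at 16–48 transverse cells ×
60–500 axial steps (the mesh-independence study itself demonstrates
resolution sufficiency), PTT cycle integrations at 256–512 samples per
cycle.
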