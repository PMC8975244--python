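# Methods

This note documents the models, estimators, numerical choices, and known
limitations of `memprobe`. Everything stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is asserted beyond what the
code demonstrates.

## Physical picture

A rigid nanorod (length l ≈ 140 nm) adheres prone to a lipid bilayer — a
giant vesicle of radius R ≈ 7 µm or a cell plasma membrane — and its 3D
orientation û(t) is tracked polarimetrically at several kHz with ~1°
precision. The rod rotates quickly within the membrane plane while the
plane itself (the local normal n̂) wobbles with the membrane's bending
undulations. Three layers of information are extracted:

1. **Lateral diffusion**: the 3D MSD of the rod on the vesicle sphere is
   4·D_t·τ at short lags and saturates at 2R² (chord-squared bound).
2. **In-plane rotation**: the physical MSAD grows as 4·D_r·τ; D_t and D_r
   together determine the membrane surface viscosity η_m and the effective
   rod length through a membrane-hydrodynamic drag model.
3. **Out-of-plane wobble**: the lag dependence of the normal's angular MSD
   is a band integral over undulation modes and carries κc, σ, and the
   intermonolayer friction b.

## Fluctuation model

Static spectra use the Helfrich equipartition forms ⟨|h_q|²⟩ =
kBT/(κc q⁴ + σ q²) and ⟨|θ_q|²⟩ = q²⟨|h_q|²⟩. The out-of-plane MSAD
integrates the tilt spectrum over the resolvable band [π/R, 2π/l] with a
two-exponential per-mode time factor whose weights are κc/κ̃c and
1 − κc/κ̃c, κ̃c = κc + 2εd².

The rates ω₁(q), ω₂(q) are the eigenvalues of the coupled
height/monolayer-density relaxation: free-energy Hessian

    E(q) = [[κ̃c q⁴ + σ q², −2εd q²], [−2εd q², 2ε]]

with mobilities 1/(4ηq) for the height (bulk hydrodynamic damping) and
q²/(2b + 2η_m q²) for the density difference (intermonolayer friction,
optionally monolayer surface viscosity — a pluggable choice; over the
experimental band η_m q² ≪ b, so the variants are indistinguishable there).
Branch labeling matters because the model fixes the weights: ω₂ is the
branch whose exact height-autocorrelation amplitude is closer to κc/κ̃c.
In the decoupled limit εd² → 0 this reduces ω₂ to the classical
bulk-damped bending rate (κc q³ + σ q)/(4η), which is the guard test
against mislabeling. The branch assignment switches at the avoided
crossing of the two rates (q ≈ 9×10⁵ m⁻¹ for the standard parameter set),
so the band quadrature — Gauss–Legendre on ln q with node doubling to a
1e-8 relative tolerance — splits the band at the located switch points.

**Angle conventions.** The model quantity is the squared angular
displacement of the normal *direction* (equivalently the MSD of the
two-component tilt vector of n̂ about the radial direction). Its τ→∞ limit
equals 2⟨θ²⟩ with θ the scalar polar angle, because the vector correlation
decays to zero while the scalar product ⟨θ(t)θ(t+τ)⟩ would not (θ ≥ 0 has
nonzero mean). Estimators therefore compute the tilt-vector MSD for the
out-of-plane curve and the scalar mean square for the variance route.

**Rotational diffusivity convention.** D_r is defined operationally through
the short-lag slope of the physical MSAD, ⟨Δφ²(τ)⟩ = 4 D_r τ; the prone-rod
generator uses Var(Δφ) = 4 D_r Δt per step, and the drag model absorbs the
convention (it was checked for joint consistency against the measured
quadruple D_t, D_r, η_m, l_eff of the tense vesicle experiment).

## Octant folding

Polarimetric tracking loses the sign of every orientation component,
folding û into one octant. The raw (folded) MSAD is bounded — for a planar
rotor phase-averaged over the fold boundaries it saturates at 2 − 16/π² ≈
0.379 — and is mapped back to the unbounded physical MSAD by a tabulated
monotone forward map built by dense quadrature over the stationary phase
and the Gaussian step (a Monte Carlo variant averaged over random plane
orientations is available as `tilted_rotor`). The map is inverted by
monotone PCHIP interpolation; raw values at or above saturation are flagged
unmappable, never extrapolated. Folding losses scale as √m (the fraction of
phases within a step of a fold boundary), so the map approaches the
identity at small displacements but the correction is already ~9% at
0.01 rad².

Folded data determine a plane normal only up to the signs of its
components; the windowed SVD plane fit resolves the branch with the outward
radial anchor on vesicles, or window-to-window continuity otherwise, and
reassigns per-sample signs against the current normal iteratively (with a
coarse hemisphere grid search as fallback). Windows with nearly collinear
orientations are flagged invalid.

The plane-fit procedure assumes the normal moves slowly compared with the
in-plane rotation over one window (default 20 samples). At the full
experimental band this holds only partially — the high-q tilt modes relax
within single frames — and the median inference error on synthetic vesicle
data is then ~8–9°; in the validity regime (band limited to slower modes)
it is 1–2°. The membrane Monte Carlo validation (below) gives 2–6°.

## Estimators

Lag statistics use overlapping pairs on log-spaced lag grids (~15 per
decade). Standard errors divide the pair dispersion by an effective count
of non-overlapping pairs (n_pairs·dt/τ), the standard block-decorrelation
practice in single-particle tracking. The covariance estimator records the
per-lag pair variance so that ⟨Δθ²(τ)⟩ = 2A(0) − 2A(τ) holds exactly on
the same pair sets.

## Fits

- Diffusivities: weighted straight-line fits through the origin; the
  translational fit restricts lags to τ < 0.01 R²/D_t self-consistently;
  the rotational fit uses the shortest decade and flags a local log-slope
  below 0.9 as subdiffusive.
- Membrane parameters: weighted least squares over
  (log κc, log σ, log b, log offset), with multiplicative-noise (log-space)
  residuals on the MSAD curve plus one residual tying the model plateau +
  offset to the variance-derived 2⟨θ²⟩. Multi-start (8 seeded starts by
  default) guards the shallow b direction. The static offset is physically
  the instrument noise floor (~2·(1°)² rad²); because it is only a few
  percent of the shortest-lag signal it is weakly identified, and the
  recovery protocol anchors it with a loose lognormal prior (factor ~2)
  at the known precision — left free it drifts and biases σ upward ~20%
  through the κc–σ correlation. χ² profiles re-optimize the other
  parameters on a log grid; Δχ² = 1 crossings give intervals, and a profile
  that does not close flags the parameter one-sided (the tension of floppy
  vesicles is upper-bounded only). Rod-length uncertainty (q_max = 2π/l)
  is propagated by refitting at l ± Δl.
- Mobility inversion: the drag backend is Saffman–Delbrück-type,
  γ_t = 4πη_m/[ln(2 l_m/l_eff) − γ_E] with l_m = η_m/η and rod effective
  radius l_eff/2, and 2D rotational drag γ_r = π η_m l_eff². γ_r fixes
  l_eff(η_m) and the remaining scalar equation is solved by Brent's method
  on the physical branch (the increasing side of γ_t along the inversion
  path, ln(2l_m/l_eff) − γ_E > 3/2). The backend is pluggable and its
  identity is recorded in every result.
- Cell case: A(τ) = A₀e^{−ωτ} fitted over τ < 5 ms by weighted nonlinear
  least squares; κc = (kBT/2πA₀)(δq/q) evaluated at both ends of the
  plausible band fraction δq/q ∈ [0.2, 0.9]. The MSD crossover detector
  finds the terminal run of lags with smoothed log-slope ≥ 0.9 (dropping
  the noise-dominated tail, relative SE > 10%) and fits 4Dτ + const beyond
  it.

## Synthetic generators

All generators take explicit seeds and are bit-reproducible. Defaults are
the study conditions: dt = 0.2 ms, 1° orientation noise, R = 7 µm,
l = 140 nm, D_t = 0.52 µm²/s, D_r = 27.7 rad²/s, kBT = 4.07e-21 J (room
temperature).

- Sphere diffusion: tangent-plane Gaussian steps + renormalization;
  uniform stationary density.
- Band modes: 64 log-spaced slices whose stationary variances are the exact
  slice integrals of the tilt spectrum (total variance telescopes exactly
  to half the plateau); each slice contributes two independent
  Ornstein–Uhlenbeck components per tilt component with rates (ω₂, ω₁) and
  variance split (κc/κ̃c, 1 − κc/κ̃c), so the per-mode autocorrelation
  matches the model bracket exactly. OU updates use the exact discrete
  transition and are valid at any dt (the fastest band modes relax within
  one frame, exactly as in the experiment — this is information loss, not
  a discretization error, so no dt guard is imposed).
- Rod-on-vesicle: sphere diffusion + mode tilt (local normal = radial
  direction tilted by the mode sum, small-tilt composition) + in-plane
  rotation in the parallel-transported tangent frame; emits ground-truth
  normals and clean orientations alongside the folded, noisy channel.
- Cell walk: harmonic corral (s.d. 40 nm per axis, i.e. ~95% of positions
  within a 200 nm diameter corral) whose center hops as a Poisson process
  (rate 3 s⁻¹, 200 nm jumps, long-time D = rate·jump²/2 = 0.06 µm²/s),
  plus an OU θ⊥ series (rate 610 s⁻¹). The single corral size means the
  short-lag MSD is diffusive rather than the broadly subdiffusive cascade
  of real cortex-corralled membranes.
- Noisy MSAD datasets: model curves with per-point multiplicative lognormal
  noise; the variance target is (plateau + offset)/2 with the same
  fractional noise.

What passing tests on these generators do *not* show: the generators share
the model's Monge-gauge, small-tilt, and single-exponential-covariance
assumptions, so recovery tests validate the estimator/fit chain, not those
modeling assumptions themselves.

## Membrane Monte Carlo

A closed triangulated surface (icosphere level 3 = 642 vertices by default;
level 4 supported) samples the Canham–Helfrich energy Σv (κ/2)(c1+c2)² Av,
with c1, c2 from a per-vertex area-weighted shape operator built from edge
dihedrals (each edge's integrated total curvature |e|·φe split evenly
between its endpoints, projected on the vertex normal's tangent plane).
A cotangent-Laplacian backend cross-validates the energy (sphere energies
agree within 1%; the continuum 8πκ is matched to 0.2% at level 3 and 0.03%
at level 4, and single-harmonic deformation stiffness matches
(κ/2)a²(l−1)(l+2)l(l+1) to 1–5% at level 4).

Moves: per sweep, N vertex displacements, E edge flips, and 60 rod
translate / free-rotate / spin triplets. Tether bounds (edge length in
[a0, √3·a0]) plus vertex self-avoidance (no pair closer than a0) maintain
surface integrity; all proposals are symmetric (the spin move rotates the
rod axis about the outward radial direction by a uniform angle — on a
quasi-spherical vesicle this is the fast in-plane rotation that the plane
fit requires). Metropolis sampling was validated directly: the marginal
distribution of a single movable vertex matches Boltzmann quadrature of its
local energy.

Excess-area states: membranes are area-incompressible, so "tense" vs
"floppy" is set by deflating the enclosed volume at (near-)fixed total
area — hard windows of ±0.5% (volume) and ±1% (area) during production,
reached during burn-in by a soft harmonic penalty inside wide windows
(the penalty is off during sampling, so it cannot bias equilibrium).
Defaults: reduced volume 0.995 (tense) and 0.85 (floppy), κ = 10 kBT
(within the measured range of the lipid systems studied).

The rod (length 3.5 a0, 9 binding sites) binds via a truncated-shifted
Lennard-Jones potential (ε = 1.5 kBT/site, minimum at a0, cutoff 3.5× the
minimum). The wide, shallow seat matters: with a narrow deep seat the rod
locks into registry with the vertex lattice and its rotation freezes — a
discretization artifact, not membrane physics. With the default seat the
rod stays bound and prone, rotates freely on the tense vesicle, and is
visibly caged by undulation valleys on the floppy one (in-plane MSAD
exponent ~0.86 vs ~1.0, lower magnitude, larger out-of-plane tilt
variance), reproducing the tension-dependent caging phenomenology. The
angle δ between the true local patch normal (faces within half a rod
length) and the normal inferred from rod orientations by the experimental
plane-fit procedure has median 2–6°.

MC sweeps are not physical time: all comparisons with experiment are
orderings and exponents, never rates.

**Known limitation — spectral rigidity at level 3.** The equilibrium
undulation spectrum follows the quasi-spherical equipartition family
⟨|u_l|²⟩ = kBT/[κ_eff (l−1)(l+2)(l(l+1)+σ̄)] with R² ≈ 0.99, but the
fitted κ_eff is systematically ~0.55–0.60 of the Hamiltonian input
(checked at κ = 10 and 20 over equilibrated 16 000-sweep runs; present
with edge flips disabled as well). Since the static mode stiffness and the
Boltzmann sampling are independently verified, this is a thermal
lattice-scale renormalization of the fluctuation rigidity at 642-vertex
resolution; the finer mesh that would reduce it does not equilibrate its
long-wavelength modes within a practical run. Quantitative rigidity
inference from the simulated spectrum therefore requires this calibration
factor; the package reports the uncalibrated fit.

Problem sizes used by the test suite and acceptance script — 10⁵-step
trajectories, 20 fit replicates, 5 000-sweep production runs at level 3 —
were chosen so every stochastic check has ≥3σ resolution at its stated
tolerance.

## Degenerate inputs and failure signals

Non-positive wavenumbers, non-unit orientations (tolerance 1e-6), points
outside the vesicle sphere, non-monotone time, and malformed table rows are
hard errors with located row numbers. Quadrature non-convergence raises a
dedicated error; saturated raw MSAD values are excluded and counted;
collinear plane-fit windows are flagged invalid; a fit with no short-lag
regime, a covariance that is not positive at short lags, or a drag
inversion with no root in the physical branch all raise with diagnostics
rather than returning numbers.
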