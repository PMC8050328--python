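# Methods

## Physical model and assumptions

The chamber is treated as a radially symmetric annulus between the aperture
radius r₁ = 350 µm and the chamber wall r₂ = 6000 µm, with a uniform, static
field of consuming cells. One molecular species at a time obeys

    ∂C/∂t = (1/r) ∂/∂r ( r D ∂C/∂r ) − n·k·f(C),
    f(C) = C_bulk · C / (C + K)

with C(r₁, t) = C_bulk (the aperture is a fixed source at the upper-
compartment concentration), zero flux at r₂, and uniform initial condition
C_bulk (the instant the chamber top is placed). Oxygen and glucose are
independent: no cross-coupling, no temperature dependence of D, no cell
death, migration or proliferation feeding back on n during a run.

The consumption law saturates at n·k·C_bulk = n·A_max (per volume). As
written, its half-saturation point sits at C = C_bulk, i.e. consumption at
the boundary concentration is A_max/2 even though k is calibrated from
A_max = k·C_bulk. Rather than resolve that tension silently, the
half-saturation constant K is an explicit parameter of `TransportParams`
defaulting to C_bulk; the generalized form f(C) = C_bulk·C/(C + K) keeps the
saturation ceiling at n·A_max for any K.

A separate one-dimensional Fick's-law column model supplies the aperture
boundary value for oxygen: a column of height L = 250 µm (chamber height plus
top coverslip), fully oxygenated at the top (C_top = 178 µM), with all
consumption confined to the bottom monolayer. At steady state the profile is
linear and the cell-layer concentration is C_top − σ·A_max·L/(N_A·D),
≈ 170.7 µM with the default parameters; this 171 µM is the C_bulk used by
the dynamic model. The closed-form linear solution is used deliberately —
the column has no volumetric consumption — rather than a discretized solver.

## Parameters

| Parameter | Oxygen | Glucose | Units | Notes |
|---|---|---|---|---|
| D | 3370 | 616 | µm²/s | diffusivity in media at 37 °C |
| A_max | 2.98×10⁷ | 6.47×10⁷ | molecules·cell⁻¹·s⁻¹ | maximum per-cell consumption (4T1) |
| C_bulk | 171 | 25 000 | µM | aperture boundary value; oxygen corrected by the column model from 178 µM |
| σ | 2×10⁵ | — | cells/cm² | plating density; n = σ/height |
| height | 100 | — | µm | chamber height for the dynamic model (138.4 µm as-built for volume) |

Internal units are µm / s / µM / cells everywhere; all conversions
(molecules↔mol via N_A = 6.02214076×10²³, cm⁻²↔µm⁻², µM↔mol/µm³, µm³↔µL) are
centralized in `reecsim.units` because the source parameter conventions mix
unit systems and silent mixing is the dominant correctness risk.

Derived defaults: k = A_max/(N_A·C_bulk) ≈ 289.4 µm³·cell⁻¹·s⁻¹ for oxygen,
n = 2×10⁻⁵ cells/µm³, λ = sqrt(D/(n·k)) ≈ 763 µm. The consumption timescale
1/(n·k) ≈ 173 s is short against the 48-h horizon, which motivates the
implicit integrator below.

## Numerical scheme

Vertex-centred finite volume on a uniform radial grid (default spacing
10 µm, warned if coarser than λ/10), with cell volumes ½(r²_{i+½} − r²_{i−½})
and face conductances D·r_{i+½}/h, so the discrete operator is conservative
in the cylindrical measure. Time stepping is backward Euler; the consumption
term is linearized about the previous step as n·k·C_bulk/(C_prev + K)
multiplying the new concentration, which makes each step an M-matrix
tridiagonal solve — unconditionally stable and positivity-preserving — and
converges to the exact nonlinear steady equation at the fixed point. The
Dirichlet row is scaled like its neighbours to keep the system
well-conditioned. Default dt is the inspection interval (60 s), subdivided
to divide it evenly if a smaller dt is requested.

Numerical policies:

- concentrations below −10⁻⁹·C_bulk abort with a solver error (instability);
  smaller negatives are round-off and are clamped to 0; the analogous
  round-off trim is applied at the C_bulk ceiling (maximum principle);
- convergence is declared when the RMS change between profiles one
  inspection interval apart, normalized by C_bulk, drops below 0.1%. The
  cadence matters: at the 60-s default the criterion fires while the profile
  is still ~2×10⁻³·C_bulk from the fixed point (the slowest relaxation mode
  has a ~110 s timescale); self-consistency checks that need the criterion
  to genuinely bound distance-to-steady use a 600-s cadence;
- fronts extracted from concentration profiles take the smallest radius at
  which C first reaches the threshold, linearly interpolated between nodes,
  and are reported as distance from the aperture edge (r − r₁); radii
  themselves are absolute from the chamber centre.

Two independent routes cross-check the marcher: with f(C) = C the steady
problem is a modified Bessel equation with closed form
C(r) = C_bulk·[I₀(r/λ)K₁(r₂/λ) + K₀(r/λ)I₁(r₂/λ)] / [same at r₁], evaluated
with exponentially scaled Bessel functions; the nonlinear steady ODE is also
solved by collocation (`scipy.integrate.solve_bvp`) sharing no code with the
marcher. At default resolution the marcher agrees with the closed form to
~10⁻⁴ max relative error (run to a tight 10⁻⁸ tolerance so the slowly
relaxing outer tail is converged too) and with the BVP solution to ~0.3% RMS
at the default stopping tolerance; halving the grid spacing moves the steady
profile by ~10⁻⁵ RMS.

## Profiling conventions

Segmented data arrive as per-cell tables (id, x/y in µm, one column per
channel). Conventions that the data themselves cannot carry are fixed as:

- bin edges are half-open [lo, hi), width 50 µm by default, starting at 0 at
  the aperture centre;
- empty bins are gaps (NaN), never zeros, and aggregation across replicates
  skips gaps per bin rather than imputing;
- SEM of a single-cell bin is undefined (NaN) — deliberately distinct from
  the 0 of a multi-cell bin with identical values;
- cells beyond a caller-supplied maximum radius (e.g. outside the chamber,
  which real stitched mosaics do contain) are excluded with a logged count;
- smoothing is a centred moving average whose window truncates at the
  profile ends; 5 points by default;
- front detection scans outward for the first bin at or above
  fraction·max (0.9 by default), interpolating linearly between bin centres;
  exact ties resolve to the smaller distance; a profile already above
  threshold in its first bin fronts at that bin centre;
- the pixel-based radial profile bins per-pixel radii at the same 50 µm
  rather than averaging at each exact radius; on smooth images the
  difference is below half a pixel spacing;
- disk areas come from mask pixel counts × pixel area, or π·radius² when a
  measured radius is supplied.

## Synthetic data: what it does and does not emulate

The generator reproduces the *structure* of chamber data — radially
symmetric concentration-dependent fluorescence with multiplicative
log-normal noise (σ = 0.2 by default), spatial Poisson cell placement at the
experimental plating density (2×10⁵ cells/cm², ~2.3×10⁵ cells per chamber),
phenomenological disk formation (density interpolating from uniform to a
logistic-edged disk; a description of the end state, not a mechanism), and
images as Gaussian spots with optional checkerboard tile modulation and shot
noise. All randomness derives from one integer seed through per-operation
`SeedSequence` substreams, so fixtures are bit-reproducible.

It does **not** emulate: segmentation errors, background structure,
flat-field or rolling-ball artifacts, real reporter photochemistry (the
default response I = I_max·(1 − C/C_bulk) and the sigmoidal alternative are
conventions, not fits — no quantitative dose–response for these reporters is
available), cell-cycle or death dynamics, or chamber-to-chamber geometry
variation. Passing pipeline-recovery tests therefore demonstrates that the
measurement chain is unbiased and stable *given* those modelling choices; it
does not validate the reporter model against real chemistry.

## Front fold change under reduced consumption: a geometric caveat

Reducing A_max 4-fold doubles λ. In planar geometry that would exactly
double the distance to any fixed relative threshold, and a 2-fold front
shift is the intuition often attached to consumption-halving interventions
(e.g. cytokine-stimulated macrophages with suppressed oxygen consumption).
In the chamber's cylindrical geometry the intuition fails quantitatively:
the steady tail decays like K₀(r/λ) ≈ e^{−r/λ}/√r, and the fixed aperture
radius offsets both distances, so the measured fold change of the
90%-of-max front is ≈ 1.65, not 2.0 — at steady state and equally at the
2-h time point (both conditions are quasi-steady well before 2 h; the
slower-consuming chamber's far field equilibrates on a ~1/(n·k/4) ≈ 700 s
local timescale). The acceptance script reports the measured value; the
corresponding test asserts the 2-fold band and is expected to fail, which we
keep visible rather than repairing, because it documents a real geometric
effect: observing a clean 2-fold in a chamber experiment implies more than a
pure 4-fold consumption drop.

## Problem sizes

Defaults were chosen so a full run is interactive on one core: 566 radial
nodes (10 µm spacing), 60-s steps over at most 48 h simulated (the default
oxygen case converges in ~25 minutes of simulated time), 50-seed recovery
ensembles of ~2.3×10⁵ cells each. The complete test suite runs in ~15 s and
the acceptance script in ~10 s.

## Known limitations

- The consumer field is static; real disks change density over days, so
  late-time profiles of a real chamber reflect a moving target the model
  does not track.
- The aperture is modelled as a fixed-concentration ring at r₁; the true 3-D
  flow through the hole (and the column above it) is reduced to the 1-D
  column correction.
- The RMS convergence criterion bounds successive change, not distance to
  steady; interpret `convergence_time` accordingly (see cadence note above).
- Glucose behaves qualitatively differently from oxygen under the same
  model: λ_glucose ≈ 2.7 mm is comparable to the chamber radius, and on the
  hours timescale of gradient formation glucose barely moves (≥ 72% of the
  25 mM media value everywhere at 2 h, when the oxygen field is already
  quasi-steady). Over the full 48-h horizon, however, the model does deplete
  the far field substantially (to ~13% at the wall), and the RMS convergence
  criterion fires long before that slow drift ends because changes per
  minute are tiny relative to 25 mM — another reason to treat
  `convergence_time` as criterion-specific, not as physical equilibrium.
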