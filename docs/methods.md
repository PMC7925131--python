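# Methods

This note documents the quantitative machinery in `colonyscreen`: the
models and procedures, their assumptions, the defaults and why they were
chosen, and what the synthetic-data generators do and do not emulate.

## Ratiometric quantification of co-culture colonies

**Problem.** A co-culture colony is spotted from a 1:1 mixture of a
GFP-labeled knockdown strain and an RFP-labeled parent strain. After
growth, the GFP fraction `G` of the colony reports how well the
knockdown competed. Fluorescence scanners do not report `G` directly:
channel gains differ, and the GFP and RFP signals saturate differently
with composition, so the raw channel ratio `I = GFP/RFP` is a nonlinear
function of `G`.

**Calibration model.** Each plate carries a titration row of colonies
grown from known volumetric mixtures, `G = 0, 0.1, ..., 1.0`. The
titration ratios are fit to the saturating curve

    I = alpha * G / (1 - beta * G),        0 <= G <= 1,

by nonlinear least squares (`scipy.optimize.least_squares`, bounds
`alpha > 0`, `beta <= 0.999`). `alpha` is the channel-gain ratio at
`G -> 0`; `beta` captures the curvature (a linear instrument has
`beta = 0`). Initialization uses the titration point nearest
`G = 0.5` (`alpha0 = I/G`, exact when `beta = 0`) and `beta0 = 0`,
which converges from both the linear and the saturating regime. The
curve is inverted analytically per colony:

    G = I / (alpha + beta * I).

Inverses pushed outside `[0, 1]` by noise are clipped and flagged,
never silently. Calibration is per plate: scanner gain and agar
autofluorescence vary between plates, and each plate carries its own
titration row.

**Intensity extraction.** Plates are segmented into one pitch-sized
(9 mm) square cell per colony; the cells tile the scan exactly.
Within a cell, background is the median of a border-pixel frame
(default width 10% of the cell side) — robust, local, and unaffected
by the centered colony. The intensity statistic is the
background-subtracted pixel sum over the whole cell (negative residual
pixels clipped to 0), not a segmented-mask sum: summing the full cell
is insensitive to irregular colony outlines and to how much of the
Gaussian rim a mask would capture. The ratio `I` is left undefined —
and the colony flagged — when the RFP sum does not exceed the expected
clipped-background sum by 5 standard deviations of the summed noise
(estimated from the border frame's MAD); dividing by a near-zero RFP
signal would otherwise produce arbitrarily unstable ratios.

**Competitive fitness.** Fractions are normalized per plate so the 1:1
parent-GFP : parent-RFP control co-cultures average exactly 1:

    fitness = G / mean(G over the plate's controls).

On this scale 0 means fully outcompeted and 1 means parity with the
parent. Normalization divides fractions, not ratio-derived odds; the
fraction is the quantity the calibration maps, and the control mean of
the resulting fitness is exactly 1 by construction.

**Colony size.** Monoculture colony diameter is measured automatically:
threshold at half of the background-subtracted peak, take the connected
component containing the cell center, and report its equivalent-area
diameter. Cells whose peak does not rise 5 noise-SD above background
get size 0 (a dead or absent colony).

## Synthetic plates

The generator renders what the quantification assumes and nothing
more. Each colony is a flat-top disc of radius 1.5 mm with a Gaussian
rim (sigma 0.1 mm), placed on a 9 mm grid at 10 px/mm and 16-bit
dynamic range. A colony with fraction `G` and brightness `B` gets
integrated signals `GFP = B*alpha*G` and `RFP = B*(1 - beta*G)`, so
the noiseless channel ratio satisfies the calibration curve exactly —
the generator and the fitting code share only the two-parameter
relationship, not any implementation. Colony patches are rendered with
4x4 sub-pixel supersampling so pixel sums match the analytic profile
integral to well under 1% even with sharp rims.

Noise has two parts: per-pixel additive Gaussian background (level 100,
sd 5 counts) and an independent per-colony, per-channel multiplicative
log-normal factor with CV 0.03 — colony-to-colony brightness variation
of a few percent, typical of flatbed fluorescence scans. Ground-truth
sample fractions come from a three-component mixture (30% near 0,
40% near 0.5, 30% spread over the middle) so the full calibration range
is exercised. The generator does not emulate colony morphology
(wrinkling, suppressor sectors), agar artifacts, optical point-spread,
or spatial background gradients; passing recovery tests therefore
demonstrate correctness of the quantification arithmetic and its noise
robustness, not robustness to structured real-scanner artifacts.

## Growth kinetics

OD600 curves (sampled every 7.5 min) are blanked, smoothed with a
moving median then a moving mean (both window 5 = 37.5 min,
nearest-edge padding so constant series are fixed points), and the
maximum specific growth rate is the maximum finite-difference
derivative of `ln(OD)` — central differences on interior points,
one-sided at the ends. Points at or below an OD floor of 0.005 after
blanking are masked: the log of reader noise is meaningless. The
window and floor are configurable; the defaults suppress reader noise
without flattening the exponential phase at this sampling rate.
`doubling_time = ln 2 / rate`; the default simulation growth rate of
0.0175/min corresponds to a 40-min doubling time.

The curve generator produces logistic trajectories with additive reader
noise, default sd 0.001 OD (the read-to-read precision of a modern
microplate reader) from an inoculum at OD 0.02 above blank. Because a
max-of-noisy-derivatives estimator is upward biased when the curve
starts near the noise floor, the estimator's bias is only guaranteed
small (<5% in the property tests) for curves whose early OD is well
above the floor, as these defaults are.

## Screen statistics

* **Classification**: low fitness = at least 2 sample SD below the
  reference mean; neutral = at least 1 SD above. The reference
  population is a parameter (plate controls by default, or the whole
  dataset) because both conventions are useful; the sample (n-1) SD is
  used throughout since control sets are small.
* **Media differences**: a strain is flagged when its fitness differs
  between two media by more than 0.24 at 24 hr or 0.30 at 48 hr
  (configurable per timepoint).
* **Mutualism score**: `(F_dm_48 - F_wt_48) - (F_dm_16 - F_wt_16)`,
  the growth from 16 to 48 hr of the fitness benefit a knockdown gains
  when its parent competitor cannot make extracellular matrix.
  Replicates are averaged before scoring (per-replicate scoring is
  available via the aggregation parameter). The score uses the
  plate-normalized fitness values directly; the additional
  "normalize to 0.5-day fitness" rescaling used for time-course plots
  is exposed as an option but off by default. The mutualist call
  threshold is `mean + 2 SD` of control scores; which co-cultures count
  as controls is configurable (no-sgRNA library strains, parent-parent
  control co-cultures, or both — the default uses both).
* **Inference**: two-sided pooled-variance Student t-tests and
  Benjamini-Hochberg step-up FDR adjustment (`scipy.stats`), both
  cross-checked in the test suite against closed-form and brute-force
  transcriptions of their definitions.

## Synthetic screens

`generate_screen_truth` emulates the statistical structure the screen
statistics assume: a 302-strain library (252 essential, 47
conditionally essential, 3 no-sgRNA controls) plus 19 parent-parent
control co-cultures (an 8x12 plate's outer control column and row).
Strain base fitness is 1 plus Normal(0, 0.05) jitter; 30% of
non-control strains carry a planted defect (fitness uniform on
[0, 0.5]); replicate noise is Normal(0, 0.05) with 3 replicates.
Designated mutualists gain a matrix-deficient-parent advantage growing
linearly from 0.05 at 16 hr to 0.5 at 48 hr. All effects are
condition-independent unless planted, so recovery tests measure the
statistics, not hidden generator structure. Real screens add
plate-to-plate batch effects and fitness-dependent variance that this
generator does not model.

## Reaction-diffusion colony competition model

Two strains with densities C1, C2 are inoculated uniformly in a disc of
radius r0 = 1 mm, spread in 2-D with cell diffusivity DC, and compete
for one nutrient n (diffusivity Dn) under Monod kinetics with
half-saturation K. Nondimensionalizing nutrient by its initial level n0
and densities by n0/b (b = nutrient-to-biomass yield):

    dC1/dt = M1 * n/(n + kappa) * C1 + DC lap C1
    dC2/dt = M2 * n/(n + kappa) * C2 + DC lap C2
    dn/dt  = -(M1 C1 + M2 C2) * n/(n + kappa) + Dn lap n

with kappa = K/n0. Defaults: M1 = 0.0175/min (40-min doubling),
M2/M1 = 0.8 (a 20% knockdown growth deficit), DC = 0.003 mm²/hr,
Dn/DC = 100, kappa = 0.05, initial areal density c0bar = 1e-3 per
strain inside the inoculum. Internal units are minutes and mm.

Numerics: explicit forward Euler, 5-point Laplacian, reflecting
(no-flux) boundaries on a square domain circumscribing a 6-mm radius;
defaults dx = 0.05 mm, dt = 0.1 min (inside the stability bound
`dt <= dx^2 / (4 max(DC, Dn)) = 0.125 min`), 9600 steps to 16 hr. The
inoculum disc indicator is anti-aliased over one cell. Negative
undershoots are clipped to zero and the removed mass logged (zero at
default parameters). Because the reaction terms cancel in the sum
`n + C1 + C2` and the no-flux Laplacian sums to zero, the domain
integral of that sum is conserved to floating-point roundoff — the
solver's standing self-check.

Design choices made where the formulation was open:

* **Geometry**: full 2-D Cartesian grid rather than a 1-D radial
  solver; radial symmetry of the default solution is then an emergent
  property the tests can check, and asymmetric extensions need no new
  solver. Domain size (6 mm radius) and no-flux boundaries are
  conventions; the colony stays well inside the domain at 16 hr.
* **Initial density**: each strain starts at c0bar inside the disc
  (total 2*c0bar). Competitive fitness at t = 0 is 1 either way; only
  absolute densities depend on this reading.
* **Readouts**: model competitive fitness is the ratio of integrated
  cell densities `int C2 dA / int C1 dA`. Colony radius is the largest
  radius where the azimuthally averaged total cell density exceeds 10%
  of its radial maximum — a stand-in definition, configurable.

At default parameters the 16-hr model fitness of the 20%-slower strain
is ~0.12 with colony radius ~2.1 mm, declining monotonically after
inoculation; halving dx changes the 16-hr fitness by <0.2% and the
radius by ~1%. Varying Dn/DC across [10, 1000] moves 16-hr fitness by
<10%; varying kappa across [0.005, 0.5] moves it by up to ~45% (higher
kappa throttles growth and delays nutrient exhaustion). The robustness
property test therefore asserts the qualitative claim — fitness stays
within a factor of two of its default value, far below 1 — rather than
a tight band.

## Problem sizes

Test and acceptance runs use desk-scale inputs chosen once: 8x12 plates
at 10 px/mm (720x1080 px per channel), 20 noise seeds for recovery
statistics, 16-hr model runs at dx = 0.05 mm (240x240 grid) with a
dx = 0.1 mm run for the convergence comparison, and 20-seed synthetic
screens of the full 302-strain registry.
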