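# Methods

`ablashape` is an in-silico replica of a phantom study of robotically
*configurable* microwave ablation: the probe is retracted along its axis
while power is modulated over time and distance, shaping the ablation
volume; repeatability of the resulting shapes is compared against
standard fixed-probe (ellipsoidal) ablations. This note documents the
models, the parameters that matter, and the choices made where the
design was genuinely open.

## Treatment programs and kinematics

A program is an ordered list of intervals `(power P [W], duration t [s],
retraction distance d [mm])`. Ten programs ship with the package: six
standard fixed-probe programs (OVAL, 60/100 W × 120/240/360 s, d = 0)
and four configurable ones (LONG, HOUR, TEAR, PEAR; 60 W, 600 s total).
Delivered energy is Σ P·t.

The robot cannot track speeds below 1 mm/s, so moving intervals slower
than that threshold are discretized into 2 mm retraction steps executed
in 2 s, each followed by a waiting period sized so the segment's mean
speed equals the commanded speed. Choices where the protocol is silent:

- the move comes first, the dwell second, within each segment;
- a non-multiple-of-2 mm remainder becomes a shorter final step with
  proportionally scaled move/dwell times (conservation of total time and
  distance is exact by construction);
- power is held constant across interval boundaries and keeps flowing
  during dwell periods (the generator is never paused mid-program).

The trajectory coordinate `z` tracks the **feed-zone center** (the
antenna's emission region, 18 mm above the probe tip): `z = 0` at its
deepest position, increasing toward the entry. This is the planned
target coordinate; widths, heads and tails are all measured in it. The
tip position only matters for grid-bounds checks and the cooling-sink
geometry.

## Heat-conduction model

The phantom is a water-tempered polyacrylamide cylinder (D54 × H90 mm)
whose thermochromic ink turns irreversibly magenta above 60 °C, so the
observable is the *maximum-over-time* temperature field thresholded at
60 °C. The solver integrates

∂T/∂t = α ∇²T + q/(ρc)

on an axisymmetric node-centered (r, z) grid with an explicit
conservative finite-volume stencil: symmetry at r = 0, Dirichlet 37 °C
(the water bath) on the outer boundaries. The material is isotropic and
non-perfusing; no latent coagulation enthalpy (the gel does not
coagulate) and no vaporization physics. The deposition is an isotropic
Gaussian of spread σ at the feed-zone center, normalized to η × P;
the water-cooled shaft above the feed zone is a uniform line sink.

Stability: the axis cell carries a doubled radial coefficient, so the
auto-selected step is 0.9 × 1/(2α(2/dr² + 1/dz²)) — the positivity
(maximum-principle) limit, slightly stricter than the plain 2-D FTCS
bound. User-supplied steps are validated against the same limit.

### Parameters and calibration

| parameter | default | meaning |
|---|---|---|
| α | 0.10 mm²/s | thermal diffusivity (water 0.143; soft hydrogels lower) |
| ρc | 4.0e-3 J/(mm³·K) | volumetric heat capacity, water-like |
| η | 0.30 | net fraction of *planned* power deposited as heat |
| σ | 2.6 mm | Gaussian source spread |
| feed-zone offset | 18 mm | tip → emission-center distance |
| cooling sink | 0.10 W/mm | line sink along the cooled shaft |
| ambient / threshold | 37 / 60 °C | bath temperature / coagulation threshold |

η deserves a comment: generator logs show 85–90 % of planned power at
the *generator output*; the fraction that ends up as heat in the gel is
further reduced by antenna coupling/reflection and coolant losses, none
of which are published. η, α, σ and the sink were therefore calibrated
once against the reported morphometry — fixed-probe 60 W programs
producing 20–30 mm widths, an hourglass with a clear waist, a teardrop
tapering to a narrow tip, near-uniform elongated widths (CV < 15 % over
the mid-trajectory), tails always positive, and negligible proximal
heads for programs that end in motion — and then frozen. A nonzero
default cooling sink is what reproduces the last property: without
shaft cooling the quasi-steady bulb travels with the source and leaves a
7–10 mm head even for continuously moving programs, contradicting the
observed behavior; shaft cooling also produces the proximal contour
indents seen on real samples. Verification of the stepper itself is
against the instantaneous point-source kernel
T − T₀ = E/(ρc(4παt')^{3/2})·exp(−r²/(4αt')) (with t' absorbing the
finite source spread): L∞ relative error ≈ 2 % on a 0.25 mm grid.

The default grid is the sample container (radial extent 27 mm, axial
90 mm) at 0.5 mm spacing; a 600 s program integrates in well under a
second, which is what keeps the full ten-profile study in minutes.

## Synthetic cross-sections

Samples are "cut" along the probe axis by mirroring the simulated
half-plane. The renderer stores the max-temperature level-set and
thresholds it *after* bilinear resampling to the image grid (default
0.2 mm/px), so sub-grid-cell contour shifts — precisely the per-sample
variability the study measures — survive into pixel space. The signed
distance to the contour is mapped to a linear magenta ↔ off-white HSV
blend over a 1.5 mm gradient (the phantom has no sharp color cut-off;
the reported measurement uncertainty of 1–2 mm is exactly this band),
then per-channel Gaussian noise is added. Scale, probe-axis column and
trajectory-start row travel as metadata (a JSON sidecar for PNGs);
fiducial detection is out of scope.

Per-sample variability emulates, in order of importance:

- generator output drawn uniformly from 85–90 % of planned power,
  applied multiplicatively around the range midpoint;
- 3 % relative Gaussian jitter on α (global gel-batch variation);
- a correlated random displacement of the contour (sd 0.4 mm,
  correlation length 8 mm) modeling local gel inhomogeneity — without
  it the logarithmic width–energy response compresses the first two
  sources to ~0.3 mm IQR, an order below the reported 1–2 mm spread;
- optional discrete artifacts (lateral extrusions, proximal indents)
  reproducing the outlier contours seen on real samples.

What the generator does *not* model: photographic lighting and lens
effects, cutting-plane misalignment, true dielectric (SAR) antenna
patterns, and any perfusion. Passing tests therefore demonstrate the
pipeline's correctness and the study's statistical machinery under
controlled conditions; they do not validate the thermal model against
living tissue.

## Segmentation

Per the study's method: pixels are provisionally labeled by weighted
Euclidean HSV distance to prior magenta/off-white colors, per-class
channel medians become the image-specific color model, and the final
label is nearest-median — equivalently, a threshold at the color midway
between the medians, which lands the boundary in the middle of the
rendered gradient. Choices where the method is under-specified: hue is
circular (differences in turns, shortest arc); weights default to
(w_h, w_s, w_v) = (1, 1, 0.5), down-weighting value for lighting
robustness; a single refinement pass (no iteration); exact ties go to
background (conservative). Post-processing keeps the largest
4-connected component and fills holes. Round-trip Dice against the
rendered ground truth exceeds 0.99 at default noise.

## Morphometry

Widths are the extents of the foreground run crossing the probe axis,
at 5 mm steps from the trajectory start; fixed-probe shapes have the
single point z = 0. Measurement points are multiples of 5 mm not
exceeding the trajectory length. Head = extent beyond the trajectory
end (proximal), tail = extent beyond the start (distal), both clipped
at 0. Volume is the revolved-contour disc integral
V = ∫ π(w/2)² dz (trapezoid at ≤ 0.5 mm); sphericity is Wadell's
ψ = π^{1/3}(6V)^{2/3}/A with A the lateral surface of revolution (the
study names but never defines its index).

## Statistics

Repeatability at a measurement point is the median of |wᵢ − wⱼ| over
all sample pairs — the Rousseeuw–Croux Sn family of robust scale
statistics (translation-invariant, absolutely scale-equivariant,
outlier-resistant). Noninferiority of configurable vs standard shapes
uses a one-sided Mann–Whitney U test with a 1 mm margin implemented as
a location shift (configurable values minus the margin vs standard),
α = 0.05; the exact null distribution (via the q-binomial counts) for
small tie-free samples, tie-corrected normal approximation otherwise.
The effect Δ is the Hodges–Lehmann median of pairwise differences; its
one-sided 95 % upper bound comes from inverting the U test. Points
within a sample are treated as independent observations, mirroring the
study's own caveat about the configurable group.

The sample-size procedure regenerates the study's simulation-based
power analysis: both groups normal with a common arbitrary mean and
pilot SDs (0.5 mm standard, 1.1 mm configurable), group-size ratio 0.5
(standard : configurable), smallest n whose Monte-Carlo rejection rate
reaches the target — "100 % probability of significance" is read as
power ≥ 1 − 1/reps. Common random numbers keep power monotone in n for
a fixed seed batch. An ordinary least-squares regression of pooled
repeatability on commanded probe speed (speed 0 wherever any dwell
occurs at that z) reports slope, 95 % CI and R².

## Reproducibility and problem sizes

A single global seed fans out through `numpy.random.SeedSequence` to
per-profile and per-sample streams; reruns are bit-identical including
CSV output. Default study size is the full ten-program table at six
samples per program (≈ 47 measurement points), which runs in a few
minutes on one CPU; the solver-verification grid is 0.25 mm, the
production grid 0.5 mm. Known limitations: absolute widths run ~20 %
above the reported medians (the acceptance surface is property-based,
not a fit to the physical experiment); the speed–repeatability
regression has no built-in mechanism in the generator, so its slope is
reported but carries no effect by construction; and the Mann–Whitney
shift construction assumes comparable distribution shapes between
groups.
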