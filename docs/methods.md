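# Methods

This note records the models, conventions and numerical choices behind
each stage of the pipeline, what the synthetic generator does and does
not emulate, and the known limitations.

## Coordinate and unit conventions

Image convention throughout: x rightward, y downward; physical position
in µm = pixel index × pixel size. Contours are stored counterclockwise,
defined as positive shoelace area in this frame. Times are in seconds,
lengths in µm (cortex thickness in nm), pressures in Pa, tensions in
pN/µm (1 Pa·µm = 1 pN/µm exactly, so no unit conversion factor appears
in the Young–Laplace formula).

## Synthetic wave cells

The deformation model is a single sinusoidal mode in polar form around
the cell center,

    r(θ, t) = R + A·cos(2πt/T − mθ + φ₀),

with radius R (10–30 µm, the blastomere range), amplitude A, period T
(50–200 s, the physiological band), integer wave number m, and optional
additive radial Gaussian noise. The real waves' spatial profile is not
known beyond their periodicity; a single sinusoid is the minimal
traveling-wave model, and superpositions can be built by summing radial
deformations. The ground truth attached to each series includes the
phase velocity 2πR/(mT) — one wavelength (perimeter/m) passes a fixed
surface point per period.

Defaults mirror the emulated acquisition: 5 s frame interval, ~10 min
records, contour resampling to 0.25 µm arclength steps. The number of
frames is round(duration / frame_interval), with frames at t = 0,
Δt, …; a caller who wants a velocity record of exactly k periods (PIV
produces N−1 samples from N frames) uses duration = k·T + Δt.

Movie rendering rasterizes a bright membrane ring along the contour
plus an interior speckle texture. Speckles are seeded once in polar
coordinates (ρ = fraction of the local boundary radius, angle φ) and
advected by keeping ρ fixed: their displacement follows the local
boundary displacement, tapering linearly to zero at the centroid. This
is a **rendering convention chosen to give PIV-visible interior
motion**, not a model of cytoplasmic flow. Sub-pixel positions are
deposited with bilinear weights so sub-pixel motion survives
rasterization, then blurred with a Gaussian (default σ 0.4 µm). A low
uniform interior plateau guarantees inside-over-outside contrast.

Not emulated: photon (Poisson) noise, point-spread blur anisotropy,
multi-cell embryos, cell–cell contacts, apical domains, mitosis,
whole-cell rotation or translation, out-of-plane motion. Passing tests
therefore demonstrate correctness of the measurement chain under its
own geometric assumptions, not robustness to every imaging artifact.

The aspiration generator grows the tongue linearly with pressure,
reaching the pipette radius exactly at P* = 2γ(1/Rp − 1/Rc); pressure
steps bracket P*. The cortical-ring generator has an exactly Gaussian
radial cross-section with σ = FWHM / (2√(2 ln 2)) on a constant
background. The labeled-ratio generator draws from two Gaussians
truncated at zero.

## PIV

Two passes of FFT-based cross-correlation of mean-subtracted square
windows (normalized by window standard deviations; the normalization
does not move the peak), default 20 µm coarse and 10 µm fine windows at
50 % overlap — with 10 µm windows at 50 % overlap the vector spacing is
5 µm, giving ≈ π·42.5²/25 ≈ 180 vectors over an embryo-sized disk. The
coarse-pass displacement field is linearly interpolated onto the fine
grid and rounded to integer pre-shifts of the second frame's windows;
the fine residual is added back. Sub-pixel peak location uses the
three-point Gaussian fit, falling back to a parabolic fit when a
neighbor is non-positive. The search range is limited to half a window.

Featureless (zero-variance) windows yield invalid vectors, not errors.
No window deformation, no outlier replacement by default (an optional
normalized-median filter only flags). Velocities are displacement per
frame pair divided by the frame interval, scaled to µm/s; px/frame is
available by flag. Time series keep grid points valid in ≥ 90 % of
pairs and linearly interpolate sporadic gaps in time.

The engine analyses one focal plane per movie; plane choice is the
caller's. No pre-processing (e.g. contrast equalization) is applied.

## Spectral oscillation call

Each trace is mean-subtracted and transformed with a plain DFT — no
taper, no zero-padding, no detrending — with power normalized as
|X_k|²/N so the two-sided power sums to N × variance (Parseval). The
per-recording spectrum is the bin-wise arithmetic mean over all vectors
and both components. Detection: peak power among bins with period in
the band (default [50, 200] s, endpoints inclusive), background = mean
power over **all** positive-frequency bins including the peak (the
literal reading of "mean of the power spectrum"; flags restrict the
mean to the band and/or exclude the peak bin), oscillating when
peak/background ≥ threshold (default 1.777). Ties at the peak go to the
lower frequency, i.e. the longer period. The DC bin is excluded
everywhere (it is zero after mean removal).

Attainable periods are record_length/k for integer k; the CLI warns
when a requested ground truth is off this grid. A constant trace
returns an all-zero spectrum with a degenerate flag and a
not-oscillating call with reason "degenerate" — constancy is judged
with a relative tolerance (1e-12 of the trace magnitude) so float-level
noise does not masquerade as signal.

Threshold calibration sweeps candidate cutoffs at midpoints of
consecutive sorted unique ratios, computes the ROC, integrates AUC by
trapezoid over the properly ordered staircase, and selects the cutoff
maximizing Youden's J (sensitivity + specificity − 1), ties to the
lower threshold — Youden is the operationalization of "minimize false
positives and false negatives" among the standard cutoff criteria. The
1.777 default itself is a configuration constant from the original
embryo calibration, not something synthetic data can reproduce.

Stage bookkeeping ("early" = first half of a stage, "late" = second
half) is a metadata tag on calls. Records containing divisions are
excluded by the caller (no automatic mitosis detector).

## Curvature kymographs and wave velocity

Masks are optionally Gaussian-blurred (default σ 0.5 µm; the
segmentation smoothing magnitude is a free choice) and contoured by
marching squares at level 0.5, then resampled to one-pixel arclength
steps. Curvature at each point is the signed Menger curvature of the
triple (point − strip/2, point, point + strip/2) along arclength;
because the contour is uniformly resampled, the strip endpoints are
actual contour vertices at a fixed index offset — this keeps the
estimator exact (to float precision) on circles, whose sampled vertices
are cocircular. Positive curvature = locally convex (outward bulge).
Collinear triples give zero. A `boundary_average` flag instead averages
the profiles evaluated at the two strip endpoints, an alternative
reading of averaging the strip-boundary fits; the default is one fit
per strip center.

The finite strip biases curvature at features sharper than the strip:
at an ellipse vertex with radius of curvature 3.3 µm a 10 µm strip
underestimates κ by ~26 % (the exact circumcircle through points ±5 µm
of arc away). Tests pin the estimator to that dense-sampling oracle and
verify convergence to the closed form as the strip shrinks. For
blastomere-scale waves (radii 10–30 µm) the bias is percent-level.

Kymographs resample each frame's profile onto n_bins (default 360)
equal normalized-arclength bins, anchored per frame at the contour's
crossing of the +x ray from its centroid; this makes the kymograph
invariant to the contour's starting index and keeps frames with
changing perimeter registered. Known limitation: whole-cell rotation
appears as apparent wave motion under this registration; the synthetic
tests use non-rotating cells.

The temporal period is the band-limited argmax of the 2D FFT power of
the mean-removed kymograph summed over spatial frequencies, so the
period definition coincides with the 1D PIV-route definition, and the
same peak/mean call applies. Degeneracy is judged on temporal variation
only (a static cell's discretization texture along arclength carries no
oscillation). The wave estimate takes the dominant in-band component
(f*, k*) with k ≠ 0: wave number |k*|, period 1/f*, velocity
(median perimeter / |k*|)·f*, direction from the sign of k* (positive
temporal frequency pairs with spatial index −m for a wave traveling
toward increasing arclength). When the counter-propagating partner
carries within 10 % (configurable) of the dominant power the pattern is
declared a standing wave and no velocity is reported. The 2D-FFT
estimator replaces a manual line fit on the kymograph; a Radon-type
slope fit was considered and rejected as redundant, since on synthetic
ground truth the dominant-component estimator already recovers velocity
within a few percent and has no free parameters.

## Micromechanics

Critical pressure: default is the literal stepwise reading — the first
pressure whose tongue length reaches Rp — which quantizes γ to one
pressure step; interpolate mode refines by linear interpolation in
(length, pressure) and recovers a noiseless synthetic tension within
1 %. A series whose very first step already exceeds Rp returns that
step with an "under-resolved" warning. Tensions of blastomeres from one
embryo are averaged into a single per-embryo value.

FWHM: baseline is the mean of the outer 20 % of samples on each side;
half-max = baseline + (peak − baseline)/2; width between the two
half-max crossings nearest the peak, located by linear interpolation;
peaks must exceed the baseline by a relative margin (1e-9) so
float-level interpolation noise on flat profiles is not a peak. Line
scans sample the image bilinearly along the outward surface normal
(default 3 µm span, 0.5 µm spacing along the contour, 50 nm steps);
lines leaving the image or lacking a peak are dropped, at least 10
usable lines are required, and the aggregate is their median (robust to
scans crossing contacts or debris; mean by flag). Whether the original
external thickness tool aggregates per line or on a mean profile is not
documented; per-line median is the default here and both are available.

## Statistics

Detection proportions are compared with a plain chi-squared test on the
2×2 table (no continuity correction, matching the standard spreadsheet
calculation); periods and tensions with a two-sample Student t test
whose tail must be declared explicitly per comparison. Significance is
flagged at p < 0.01. These are reporting plumbing, not the package's
contribution.

## Problem sizes in the test suite

The suite and the acceptance script run on desk-scale synthetic data
chosen to exercise every code path: movies of 91–149 px frames and
120–129 frames (one cell, 8/4/6 wave periods), 360-bin kymographs,
921-px cortical rings, n = 200 ROC sets. The full suite runs in well
under a minute on one CPU.
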