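# Methods

This note documents the models, algorithms and design choices behind
`oculoflow`, what the synthetic generator does and does not emulate, and the
numerical conventions a user should know before trusting or extending the
measurements.

## Coordinate and unit conventions

Pixel coordinates are 0-based `(row, col)`; physical coordinates are
micrometres; times are seconds from the first frame; velocities mm/s; flows
nL/s; densities cells/mm²; changes are percent relative to baseline. Spatial
calibration derives from the scan field: a field of `field_size_deg` degrees
of visual angle spans `field_size_deg × 34 µm/°` across the frame columns
(34 µm/° is the retinal magnification consistent with 2–5° fields covering
68–170 µm). Out-of-field pixels created by registration are NaN sentinels
and are excluded from every downstream average rather than zero-filled,
which would darken frame edges and bias detection.

## Synthetic data

The generator produces the observable *content* of label-free retinal
videos with exact ground truth; it is the package's test bench and defines
the study conditions for validation.

**Cells.** A cell is a radial difference-of-Gaussians profile — dark core
(σ = d/8), bright annulus (σ = d/4) — at a nominal 13 µm diameter and 0.35
contrast against the background, matching the qualitative phase-contrast
appearance of leukocytes. Motion models: stationary, constant drift, or a
per-frame Gaussian random walk; positions are clamped at field edges (no
wrap-around teleporting). Ground truth records exact sub-pixel centres per
frame before eye motion and noise.

**Background.** Band-limited Gaussian texture (correlation length 8 px,
amplitude 0.05 of the mean level) emulating out-of-focus backscatter. The
correlation length is deliberately coarse relative to a cell so that the
texture anchors registration without mimicking cell-scale blobs.

**Eye motion.** Integer-rounded Gaussian translations applied periodically
(wrap-around), so the applied shift is exactly invertible and registration
recovery can be scored as exact/not-exact. Real eye motion is not periodic;
the choice affects only the few boundary columns of the synthetic frames.
Eye motion is pure translation — the animal is anesthetized and the
registration model is translational by design (no rotation/affine).

**Scan distortion.** A resonant scanner samples uniformly in time while the
beam position follows a sinusoid. The normalised forward map is
`g(u) = (1−a)·u + a·sin(πu/2)` on u ∈ [−1, 1], amplitude a ∈ [0, 1]: odd
(centre column fixed), monotone, invertible. Correction resamples through
the inverse by linear interpolation; the distort-then-correct round trip on
smooth patterns stays below 0.5 intensity units.

**Vessel kymographs.** Rows are positions across the lumen (µm/px), columns
successive line scans (default 15 kHz). Blood cells enter at one lumen edge
and follow `x(t) = x₀ + ∫ V₀(1 + m·sin 2πf_c t) dt` (closed form), leaving
Gaussian streaks (σ = 3 µm) on a brighter lumen band of the true width with
anti-aliased (1 px) edges. Pulsatility fraction m < 1 keeps the flow
direction constant; mouse cardiac frequency defaults to 6 Hz. A
configuration is rejected as unresolvable when a streak would advance more
than its own width (3 µm) per line scan.

**Vessel videos for diametry.** Pixels inside the lumen band decorrelate
from frame to frame (flowing scatterers); the surround carries a static
texture. Because the band edge is anti-aliased over one pixel, the
half-maximum of the temporal-contrast profile falls on the true lumen edge
by construction, letting diametry be validated at sub-micron tolerances.

**Conserved cohort.** For the longitudinal statistics, paired
arteriole/venule series share the same true flow change per replicate and
visit: a mean inflammatory profile (0, +30, +67, +25, +10 % across
baseline/6 h/24 h/72 h/10 d) scaled per replicate-and-visit by a Gaussian
factor (SD 0.4 — a +67% peak with ±27% cohort SD), multiplied by a 15%
session-to-session physiological flow fluctuation shared by the vessel pair
(cardiac output and anesthesia depth vary between imaging sessions; since
it is real flow, conservation still holds). The venule realises its flow
change by dilation at constant velocity, the arteriole by a velocity
increase at constant diameter. Measured velocities carry 5% multiplicative
noise. Under these conditions the venule-vs-arteriole ΔQ% fit gives a
median R² of ≈ 0.9 over 100 seeds (1.0 noiseless); each run recomputes it
from fresh simulations.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: fluorescence channels, leukocyte rolling and
transendothelial-migration morphology, pseudopod remodelling, line-by-line
temporal skew within a frame, non-translational eye motion, photoreceptor
mosaic structure, and cell appearance variability beyond the single
difference-of-Gaussians profile. Recovery results bound algorithmic error,
not biological segmentation difficulty.

## Registration

Shifts are estimated by FFT cross-correlation of low-passed frames
(Gaussian σ = 5 px, periodic boundary — consistent with the FFT's own
periodicity, so integer shifts stay exactly recoverable). The low-pass makes
the estimate anchor on the static coarse background rather than on sparse
bright cells: a few cells drifting coherently must read as cell motion, not
as eye motion. Sub-pixel refinement (upsampled correlation) is available but
off by default; integer estimation is exact for integer shifts with
sufficient texture. The reference frame defaults to the median-sharpness
frame of the first second (robust to transient blinks/opacity at either
sharpness extreme). Averaging uses window-centre timestamps; the stride
defaults to the window (non-overlapping blocks), reconciling a "first 25
frames (5 s)" counting convention with 25 fps raw acquisition — 25 averaged
frames at 5-frame/5-stride span exactly 5 s; stride 1 gives display-style
running averages.

## Detection

Both detectors satisfy one contract: frame → probability map in [0, 1],
thresholded at ≥ 0.90; 8-connected suprathreshold components above a
minimum area become detections.

**Learned heat-map regressor.** Features per pixel: the contrast-normalised
frame, Gaussian smooths at scales tied to the cell radius (r/4 … 1.5r),
their consecutive differences (DoG), scale-normalised Laplacians, and a
background-flattened matched-filter response (see below). Ridge regression
(closed form, λ = 1e-3) maps features to a centroid-derived label map —
unit-peak Gaussians (σ = radius/2) summed and clipped to [0, 1]. The raw
regression output is then probit-calibrated: the centre is the largest
background residual on the training frames and the scale places the lower
decile of training peak responses at ≈ 0.995. A plain gain cannot satisfy
both "true peaks ≥ 0.9" and "background < 0.5" because the linear readout's
peak-to-background ratio is only ≈ 1.7 on this data; the monotone probit
recalibration preserves the detection ordering while separating the two
regimes. Training is deterministic (normal equations; no stochastic
optimiser), so a fixed config reproduces identical weights.

**Classical matched filter.** The normalised frame is flattened (minus a
cell-diameter Gaussian blur), correlated with the zero-mean unit-norm cell
template, and the response high-passed at half the cell diameter —
smooth texture leaks through the matched filter but its response is
spatially smooth, whereas cell peaks are sharp, so the high-pass separates
them. The response is standardised by its own median/MAD and squashed
through Φ((z − 5)/2). No training data is needed; this detector
cross-validates the learned one and removes any trained-weights dependency
from the validation suite.

**Localisation.** Probabilities saturate at 1 over a cell core, which would
quantise component centroids to the pixel grid; detections therefore carry
the unbounded response map, and the centroid is refined by separable 3×3
parabolic interpolation at the response peak (≈ 0.05 µm accuracy on clean
frames; ≈ 0.2 µm on 5-frame averages). Flat components (no interior peak)
fall back to the geometric centre.

**Minimum area.** Components are measured on the *probability map*, where a
cell of diameter d appears as a Gaussian peak of σ = d/4; the default
minimum area is the ≥ 0.9 footprint of an ideal 6 µm cell's label kernel
(≥ 2 px) — it rejects single-pixel noise while staying below half a nominal
cell. A fixed-size disk criterion in image space would reject every true
detection at this threshold.

**Counting.** The cell count of a video is the mean number of detections
over the first 25 averaged frames; density divides by the field area in
mm². Scoring against truth uses greedy nearest-first matching at a 5 px
radius (≈ 1.5 µm at the paper-scale calibration, well under a cell radius).

## Tracking and motility

Greedy mutual-nearest-neighbour linking between consecutive frames:
candidate pairs sorted by distance (ties broken by lowest track id, then
detection order — fully deterministic), linked when both ends are free and
within 13 µm (one nominal cell diameter per averaged-frame interval; immune
cells move far less than a diameter per 0.2 s). Unmatched detections seed
new tracks; a configurable gap tolerance (default 0) lets tracks survive
missed detections. QC flags any track whose largest step exceeds 5× its own
median step — the signature of a link that hopped between neighbouring
cells — automating a manual visual-rejection step; flagged tracks are
excluded from metric summaries by default.

Displacement is the Euclidean distance between the samples nearest the ends
of a 100 s window anchored at the track's first sample; the confinement
ratio divides it by the summed step lengths over the same window, is ≤ 1
always, equals 1 only for collinear monotone motion, and is reported as NaN
(undefined, never 0) when the path length is zero. Tracks shorter than the
window raise unless an explicit override requests the full-span value.

Motility validation isolates tracking kinematics: the drift-recovery study
(0.1 µm/s over 100 s → 10.0 µm) runs without eye-motion jitter, because
registration accuracy is validated separately and a single ±1 px
registration residual at a window endpoint would otherwise dominate the
±0.5 µm displacement budget. Registration, detection and linking still run
in full.

## Velocimetry

Per time window (default 10 ms), the streak slope is the orientation of the
smallest-eigenvalue eigenvector of the structure tensor, with gradients from
derivative-of-Gaussian filters (σ = 1 px — plain finite differences
attenuate the fast-varying axis of steep streaks and bias the slope by up to
±25%; at σ = 1 the estimator is unbiased to ≈ 1% across 2–40 mm/s).
Velocity is `slope × µm/px × line rate`. Two measures keep the tensor
clean: each row's temporal mean is subtracted (static structure — lumen
band, walls — would bias the orientation horizontal), and the tensor is
accumulated only over the lumen interior (largest bright run of the
temporal-mean profile, trimmed 20% per side) because streaks appear and
vanish abruptly at the lumen edges and those sharp temporal events
otherwise inflate the time-axis gradient energy (a +8–16% speed bias).
Gradients are still computed on the full window so filter boundary effects
stay outside the accumulation region.

The tensor estimator is exactly antisymmetric under mirroring of the space
axis (flipping rows negates the mixed moment and nothing else), so the
velocity sign convention is structural, not numerical. Radon-transform
variance maximisation (2° coarse grid, 0.25° fine steps, parabolic peak
refinement) is implemented as `method="radon"` and agrees with the tensor
estimator to within a few percent; the tensor method is the default for its
exact sign symmetry, lack of rotation-interpolation bias and ~100× speed.

Featureless windows return NaN — never 0, which is a real measurement —
and are excluded from cycle averages. Cycle averaging takes the mean over
the largest whole number of cardiac cycles (≥ 2 required), which cancels
the sinusoidal pulsatility component exactly; truncation to whole cycles
keeps the bias below 1% for any span ≥ 2 cycles.

## Diametry and flow

Motion contrast is the per-pixel temporal standard deviation divided by the
temporal mean (gain-invariant; zero-mean pixels set to 0). The vessel axis
is fitted from the second central moments of the baseline-subtracted
contrast image (handles rotation/tortuosity); 21 profiles are sampled
perpendicular to the axis over the central 60% of the vessel at 0.25 px
steps, averaged, and the diameter is the full width at half maximum with
linear interpolation at the outermost half-max crossings flanking the peak.
The half level is midway between the peak and the median of the outer 20%
of the profile. Contrast rather than raw intensity is used because it is
robust to static wall reflectance and the cell-free plasma layer.

Flow is `Q = k·(π/4)·(D·10⁻³)²·V·10³` nL/s for D in µm, V in mm/s. The
profile factor k (centreline-vs-bulk velocity correction) defaults to 1 and
is configurable; all relative-change analyses are invariant to it.

## Longitudinal analysis

Relative changes are `(value/baseline − 1)·100`; the algebra
`(1+ΔQ) = (1+ΔV)(1+ΔD)²` holds to 1e−9 on noiseless inputs and is enforced
by tests. The conservation fit regresses venule ΔQ% on arteriole ΔQ%
(ordinary least squares; R² = squared Pearson correlation, invariant to
affine rescaling of either series). Because the pooling convention affects
R², the analysis reports both per-replicate pooling (all non-baseline
timepoints of all replicates) and cohort-mean pooling (one point per
timepoint), labelled. Cohort summaries report mean ± sample SD (n−1) with n;
SD is undefined (NaN), not 0, for n = 1. The Friedman test across
timepoints with replicates as blocks is delegated to the standard
implementation and reported, not reimplemented. Timepoints are ordered
categorical labels (baseline, 6 h, 24 h, 72 h, 10 d), not continuous time.

## Pipeline sizes and reproducibility

The orchestrated study (`run_pipeline`, CLI `run-all`) and the validation
suite run on one CPU: the default demo uses a 128×128 px, 150-frame cell
video and 0.4 s kymographs per vessel-timepoint (about a minute including
detector training); the drift-recovery study uses 2525 frames (101 s) to
span the 100 s displacement window. All randomness flows from a single seed
per simulation; the metrics report is byte-identical across runs with the
same config and seed (timings and paths are written to a separate run-info
file). Detector training, linking tie-breaks and all estimators are
deterministic by construction.

## Known limitations

* The detector's appearance model is matched to the generator's
  difference-of-Gaussians profile; on real phase-contrast data the learned
  detector should be retrained on manual centroid annotations, and the
  probit calibration re-anchored.
* Tracking is greedy frame-to-frame: no global assignment across gaps, no
  merge/split handling; identity swaps become likely when per-frame motion
  approaches the inter-cell spacing.
* Velocimetry assumes a single dominant streak orientation per window;
  windows mixing distinct velocities (two vessels, strong shear) return a
  weighted compromise rather than a mixture.
* Registration is translation-only and frame-global; intra-frame (line-wise)
  motion and rotation are out of scope.
* The lumen-interior localisation for velocimetry assumes the kymograph
  contains one vessel band brighter than its surround.
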