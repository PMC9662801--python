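# Methods

This note records the models, parameter choices and numerical decisions
behind each stage of the pipeline, what the synthetic generators do and do
not emulate, and the known limitations.

## Coordinate and unit conventions

Images are indexed (plane, y, x) with the origin at the top-left and x the
horizontal axis connecting the two microtissue posts; E_xx is the strain
component along that axis. ROIs are specified in micrometres and converted
to half-open, 0-based pixel windows by rounding. The pixel calibration
(μm/px) is a required configuration value: it depends on the camera/
objective pair and cannot be inferred from magnification alone. Frame rate
(30 or 15 fps), the pillar spring constant (2.68 μN/μm) and the RNG seed
live in the same flat JSON config; unknown keys are rejected.

## Regional strain

Model: the tissue patch inside an ROI deforms approximately affinely over a
beat. Given corner points X_i at a reference frame and their tracked
positions x_i, the average deformation gradient minimises
Σ‖(x_i − x̄) − F(X_i − X̄)‖²; centring absorbs translation, and the
closed-form solution is F = (x_cᵀX_c)(X_cᵀX_c)⁻¹, requiring ≥ 3
non-collinear points. The Green-Lagrange tensor E = ½(FᵀF − I) is invariant
to rigid rotation, which the tests verify directly (rigid videos register
|E_xx| < 10⁻³).

Corners are Shi-Tomasi (minimum eigenvalue of the structure tensor), at
most 200 per ROI, relative quality threshold 0.01, non-max suppression
radius 5 px. Tracking is a sparse iterative Lucas-Kanade scheme written in
this package: template windows (21 px) from the reference frame, spatial-
gradient normal matrix built once per point, bilinear sampling, Gaussian
pyramids (3 levels) coarse-to-fine, initialised from the previous frame's
solution so each registration is small. Points failing a forward-backward
consistency check (> 1 px) or with ill-conditioned gradient windows are
dropped. These parameter values are this package's defaults — the
underlying algorithms are standard but no canonical parameterisation
exists; all are configurable and logged.

Beat partitioning: peaks of the mean absolute corner displacement trace
(prominence ≥ 20% of the trace range, minimum spacing half the median peak
interval, found with `scipy.signal.find_peaks`), temporal reference points
at floor((p_i + p_{i+1})/2) — frame indices must be integral — and periods
spanning consecutive reference points, so n peaks yield exactly n−2
periods. Peak detection uses displacement relative to the video's first
frame; the strain of each period is computed relative to that period's own
first frame, with corners re-detected there. Fewer than three peaks is
reported as "no beats", not an error. An optional integer upsampling of
frames before tracking exists (default off); at the strains tested it does
not change the result.

## Twitch force

Cap templates are cut from frame 0 around user-supplied centres and
registered into each later frame by Fourier-domain cross-correlation with
matrix-multiply upsampling (sub-pixel factor 100,
`skimage.registration.phase_cross_correlation`). This was chosen over
spatial normalized cross-correlation with quadratic peak interpolation
because the end-to-end accuracy target (twitch within 1% of 2.68 μN at
0.5 μm/px, i.e. ~0.02 px) exceeds what a 3×3 quadratic refinement reliably
achieves; it is still template correlation, with a better sub-pixel stage.
Tracking is therefore relative to the frame-0 cap positions: for absolute
resting tension, the initial centres must be the true frame-0 cap centres
and an explicit unloaded rest position supplied; otherwise the rest
reference is estimated as the diastolic plateau position and resting
tension is measured as a change between days, not an absolute.

Force per pillar is k·|Δx| with k = 2.68 μN/μm; the tissue's force is the
mean of the two pillars (equal and opposite in a two-post tissue; the
convention is configurable). The diastolic baseline is the median of
frames in the lowest quartile of the force-trace range — the median is
unbiased on the flat diastolic plateau and insensitive to the few systolic
ramp frames that fall inside the band. Twitch = mean over beats of
(peak − baseline). Kinetics: time-to-peak from the force crossing
baseline + 10% of the beat's excursion to the peak; relaxation from the
peak to 50% decay; both are explicit defaults since no canonical
thresholds exist. Tissues whose two pillars' beat peaks misalign by more
than 25% of the beat period are flagged asynchronous and excluded from
twitch statistics. Twitch forces are normalized per tissue to its
pre-injury day; resting-tension changes are differences of diastolic
baselines against the pre-injury day.

## Myofibril segmentation

Per z-slice chain: (1) 4-neighbour discrete Laplacian, absolute value —
the absolute response is taken so edge transitions of both signs
contribute to the ridge over a fibril (the signed alternative splits each
fibril into two edge bands); (2) Gaussian smoothing, σ = 2 px; (3) Otsu
threshold; (4) multiplication by the Otsu mask of the median-filtered
(size 3) original slice, which removes isolated speckle detections;
(5) connected-component labelling with region properties. Segment length
is the ellipse-equivalent major axis converted to μm; segments strictly
longer than 6 μm are retained (length exactly 6 μm is excluded). Per-slice
totals are summed in μm and averaged over slices. Constant-intensity
slices (Otsu undefined) contribute zero length with a logged warning
rather than aborting the stack.

## Calcium transients

ROI traces are per-frame arithmetic means; smoothing is the two-frame
moving average s[i] = (x[i] + x[i+1])/2. Amplitude is per-beat: detected
peak value minus the diastolic level of the preceding inter-peak interval,
averaged over beats (zero when no beats are found). The diastolic level is
the median of the central half of the preceding inter-peak interval rather
than the interval minimum: the raw minimum of a noisy diastole is biased
low by extreme-value statistics (≈ −1.7σ for a 30-frame diastole), which
would alone exceed the 2% error budget the recovery tests demand, while
the median of a flat diastole is unbiased. Amplitude is ΔF, not ΔF/F₀: the
dye is non-ratiometric, and comparability across tissues comes from
normalizing to the same session's control-centre mean amplitude instead.
Mixing sessions in one normalization raises an error.

## Stains

"Auto-threshold" is mapped to Otsu. Mask subtraction is set difference on
binary masks, not grayscale arithmetic: a pixel is necrosis-only iff it is
in the necrosis mask and not in the apoptosis mask. The ratio reported is
area(necrosis \ apoptosis) / area(apoptosis), undefined for an empty
apoptosis mask. DAPI uses the median over a 150 × 250 μm centre ROI of the
maximum projection (median ≈ cell-number proxy, robust to bright debris);
vimentin/fibronectin use mean projected intensity, with max- or
sum-projection selectable.

## Hertz fitting

F = (4/3)·E/(1−ν²)·√R·δ^{3/2} with R = 27.5 μm (55 μm bead) and ν = 0.5
(incompressible hydrated tissue); units are instrument-native (μm, μN,
kPa; 1 kPa·μm² = 10⁻³ μN). The model is linear in E, so the least-squares
estimate over the loading segment is closed-form:
E = (1−ν²)·ΣF_iδ_i^{3/2} / ((4/3)√R·Σδ_i³). The contact point is taken as
pre-identified by the instrument (δ = 0 at contact); an optional 1-D grid
search over a shared depth offset is available when the export's contact
point is suspect. Unloading data are ignored. At least 5 points with δ > 0
are required; per-tissue moduli average ≥ 4 indentations (fewer is
computed but flagged).

## Synthetic data

The generators define the validation conditions; their defaults are fixed:

- **Beat waveform**: raised-cosine pulse occupying 50–60% of the beat
  period, zero outside the pulse, so every beat has a genuine diastolic
  plateau and frames at period boundaries are exactly at rest. Calcium
  pulses must be ≥ 10 frames wide (default 30 at a 60-frame period) so the
  two-frame average attenuates the peak by well under 1%.
- **Deforming video**: band-pass-filtered white noise (difference of
  Gaussian blurs, σ 1.5/6 px, rescaled to mean 128 / sd 30) gives dense
  well-conditioned corners; the true brightfield texture of a tissue is
  not characterised and not imitated. Each frame warps the base texture by
  F(t) = R(θ(t))·diag(√(1+2E_xx(t)), √(1+2E_yy(t))) about the ROI centre —
  exactly affine inside the ROI plus an 8 px margin, smoothstep-blended to
  identity (or to neighbouring ROIs' fields) outside; scenarios whose
  blend regions overlap are rejected so the truth stays exact where it is
  scored. Warping uses bilinear interpolation; at the ≤ 6% strains tested
  the interpolation bias is far below the 10⁻³ strain tolerance, which the
  oracle tests confirm. Prescribed strains emulate the observed range
  (≈ −5.5% contraction to +0.6% passive stretch).
- **Pillar video**: two dark caps (radius 20 px) on a bright background
  with error-function edges (σ 1.5 px) so sub-pixel positions render as
  near-exact translates; caps translate oppositely along x by
  baseline + peak·waveform.
- **Fibril stack**: bars are filled elongated ellipses, so an ideal
  segmentation's ellipse-equivalent major axis equals the prescribed
  length exactly (a rectangle's would be 2/√3 ≈ 1.155× longer — a
  definitional mismatch, not a segmentation error). Bars get Gaussian PSF
  blur (σ 1 px) and optional single-pixel speckle; ground truth is the
  summed length of bars strictly longer than the 6 μm cutoff. Scenarios
  for quantitative recovery avoid bar lengths within ~1 μm of the cutoff,
  where blur-induced dilation can flip inclusion.
- **Hertz curves**: the analytic force law on an 81-point 0–4 μm depth
  grid with multiplicative Gaussian noise.

What passing these tests shows — and does not. They establish the
correctness of the estimators under their own assumptions: affine ROI
deformation, translating rigid caps, additive/multiplicative Gaussian
noise, clean pulse trains. Real recordings add photobleaching, focus
drift, non-affine deformation near the injury border, overlapping
fibrils, and motion artefacts in calcium ROIs; none of these are emulated,
so quantitative accuracy on real data must be judged separately (e.g. via
the forward-backward tracking diagnostics and fit residuals the pipeline
reports).

## Problem sizes

Validation runs use 160 px-scale videos of 60 frames (three beats, one
scored period), 256 px fibril stacks of 3 slices, 4-beat calcium traces,
and 100-seed noise ensembles for the Hertz and calcium recovery checks —
sizes at which every oracle comparison is exact enough to expose
sub-percent biases while the full suite runs in about a minute.

## Known limitations

- Strain assumes affine ROI deformation; strong intra-ROI gradients bias
  F toward the corner-weighted average (no dense DIC field is computed).
- Pillar tracking measures displacement relative to frame 0; absolute
  resting tension needs an externally supplied unloaded reference.
- Stress is not computed (no cross-sectional area procedure); pillar
  mechanics enter only through the measured spring constant.
- The Hertz fit ignores finite tissue thickness, adhesion and
  viscoelasticity; it is a contact-model modulus, comparable across
  conditions rather than absolute.
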