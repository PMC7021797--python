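# Methods

`llstorm` implements the analysis chain for whole-cell 3D single-molecule
localization microscopy on a lattice light-sheet (LLS) instrument: astigmatic
3D localization of blinking emitters, correction of the sawtooth sample scan
and rotation of the skewed acquisition volume into coverslip-aligned
("biological") coordinates, sliding-window membrane density quantification,
per-dimension single-particle-tracking diffusion analysis, FRAP recovery
fitting, and experimental localization-precision estimation.  A synthetic-data
generator produces ground-truth scenes with the statistical structure the
analysis assumes, so every stage is testable without raw data.

## Coordinate model

During acquisition the sample is stage-scanned through a fixed light sheet in
a sawtooth: within one stack the scan coordinate advances by `scan_step`
(default 40 nm) per frame over `frames_per_stack` frames (default 1001), then
resets.  The camera (x, y) plane is inclined by the deskew angle α to the
coverslip, and the astigmatic z is measured normal to that plane.  The map to
biological coordinates is a rotation about the camera x-axis composed with
the scan translation s along y′:

    x′ = x
    y′ = s + y·cos α − z·sin α
    z′ =     y·sin α + z·cos α

Per frame this is rigid (unit Jacobian), so pairwise distances within a frame
and point counts — hence densities per true area — are preserved.  The
closed-form inverse is provided and round-trips to < 1e-9 relative error.

**Deskew angle.** The instrument's inclination angle is not published; the
package default is 32.45°, the conventional LLS detection-objective
inclination.  It is a plain config parameter (`geometry.deskew_angle`) and
must be set per instrument.  Whether the scan translation is applied before
or after the rotation is a convention; the composed transform above is fixed
and documented, and all internal simulation and analysis use it
consistently.

Localization precision can be estimated in either frame.  Precisions before
and after rotation are not related by a simple rotation of independent
per-axis errors (the per-axis errors mix), so the estimator is simply applied
to whichever coordinates the table carries, and the frame is reported
alongside the numbers.

## Astigmatic localization

The localizer replaces spline-interpolated experimental PSF models with the
standard elliptical-Gaussian astigmatism model — a deliberate fidelity
trade-off that keeps the engine self-contained and exactly matched to the
simulator:

- **Calibration.** Beads are detected in the central plane of a z-stack
  (≥ 9 planes), refitted in every plane, and the pooled per-plane widths are
  fitted with quartic polynomials σx(z), σy(z).  A calibration is rejected
  unless σx − σy is strictly monotone with ≥ 10 nm range (otherwise z would
  be ambiguous).  The bundled model calibration uses
  σ(z) = σ₀·√(1 + ((z ± γ)/d)²) with σ₀ = 140 nm, γ = 250 nm, d = 600 nm
  over ±750 nm — width curves of realistic magnitude for a 1.1-NA detection
  objective with a weak cylindrical lens.
- **Detection.** Difference-of-Gaussians band-pass (σ = 1.2/2.4 px), local
  maxima above `detection_threshold` robust noise SDs (1.4826·MAD), greedy
  minimum separation (4 px).  The default threshold is 4.0; the end-to-end
  density study uses 4.5 because its ~10⁸ pixels would otherwise produce
  thousands of false 4σ maxima.
- **Fitting.** Per-candidate maximum-likelihood fit of
  N·Gx(x₀, σx)·Gy(y₀, σy) + b under Poisson noise, with pixel-integrated
  (erf-based) Gaussian profiles and an analytic gradient (L-BFGS-B).  On
  noise-free spots the bias is < 0.01 px and photon counts are recovered to
  < 1%; Monte-Carlo precision follows the 1/√N shot-noise scaling.
  Non-converged fits are flagged, never silently dropped.  Overlapping
  emitters are not deconvolved (no multi-emitter fitting).
- **z assignment.** ẑ minimizes (√σx − √σx_cal(z))² + (√σy − √σy_cal(z))²
  on a 1 nm grid with parabolic refinement; ties break toward smaller |z|.
  The assignment is invalid when the minimum sits at the range boundary or
  the √σ residual exceeds 2 (width pair outside the achievable set).
  Inverting the calibration is exact to < 1 nm across the valid range.
- **Filtering.** Keep photons ≥ `min_photons` (default 500; the real
  threshold used for the published data is unstated) and |z| ≤ 700 nm (half
  the ~1.4 µm illuminated sheet range); rows with invalid z are discarded
  too.  Every filter reports its discarded count, so input = output +
  discarded at every stage.

No overcounting correction is applied in density analysis (consecutive-frame
merging is used only inside the precision estimator), matching the analysis
choice the pipeline reproduces.

## Synthetic scenes

The scene generator is the minimal geometry exhibiting the three membrane
regions quantified downstream: two spherical-cap cells (default cap radius
8 µm, height 6.4 µm) adhering to the coverslip, clipped at the mid-plane
where they would overlap so each cell presents a flat contact wall — two
apposed membranes, as at a real cell–cell interface.  Emitters are Poisson
point processes on each membrane patch with region densities in
emitters/µm²; spherical patches are sampled by thinning a full-sphere
process, so per-region counts are exactly Poisson without computing clipped
areas.  Blinking is memoryless activation (per excitable frame) with a
geometric on-time and a single bleach; dark-state recurrence is not modeled,
and the kinetic constants are free parameters (the real photoswitching
kinetics under the imaging buffers are unreported).  Image formation uses
the same astigmatic model as the localizer plus Poisson shot noise, Poisson
background, and a linear camera offset/gain (optional Gaussian read noise;
no per-pixel sCMOS noise map).  During scanned acquisition an emitter is
excitable only while it lies within half a sheet thickness of the sheet
plane, and activation clocks only over excitable frames (dye activation
requires illumination), so every membrane point receives the same expected
number of localizations regardless of position.

Because two membranes meet at the wall, the projected interface density is
about twice the per-membrane density — the geometric effect the end-to-end
test quantifies.  What the simulator does *not* emulate: real photoswitching
kinetics and duty cycles, antibody labeling geometry and efficiency
(including the reduced basal accessibility seen in real data), membrane
curvature at sub-window scales, drift, and sCMOS noise structure.  Passing
tests therefore demonstrate correctness of the analysis chain under its own
stated model, not instrument-level fidelity.

## Density quantification

Localizations in the biological frame are projected through a half-open slab
onto a region polygon and counted in square windows (default 2 µm × 2 µm)
slid on a step grid (default 0.2 µm).  Window membership is half-open per
axis (no double counting); windows not fully inside the mask are dropped
rather than rescaled, which avoids edge-ratio noise at the cost of a
window-sized margin.  Summaries report the median, the *raw* median absolute
deviation (no 1.4826 consistency factor — matching the median ± MAD
convention of the source figures), quartiles and 1.5×IQR whiskers.
Densities are per projected area; no correction is applied for membrane
inclination relative to the projection plane.  For the apical cap mask the
patch half-width is 0.33·R, which keeps the corner inclination below ~30°
and the projected-density inflation ⟨1/cos θ⟩ at ~4%.

## Tracking and diffusion

Linking minimizes total squared frame-to-frame displacement among candidate
pairs within `max_disp` (500 nm default), solved exactly per frame pair by
the Hungarian algorithm with unlinked ends costing max_disp²; gaps up to
`memory` frames (default 1) are bridged.  Per-dimension MSDs use
time-averaged overlapping pairs (this correlates successive lag points — the
standard trade-off for statistical efficiency); the ensemble MSD is the
pair-count-weighted mean over all tracks of ≥ 20 frames.  Diffusion
constants come from an unweighted ordinary-least-squares fit of
⟨Δr²⟩(τ) = o + 2Dτ on the first five lag points (a count-weighted variant is
available behind a flag).  The offset o estimates 2× the squared static
localization error and may legitimately fit negative on noisy data; it is
reported as-is with a warning.  Only the single-component free-diffusion fit
is implemented; anomalous-diffusion or mixture models are out of scope.

## FRAP

Traces (default 1.5 s frame interval, 120 s, bleach after 3 pre-bleach
frames) are normalized to the background-subtracted pre-bleach mean and
fitted with the single-exponential recovery
I(t) = I₀ + MF·(1 − I₀)·(1 − exp(−(t − t_b)/τ)).  The exponential model is a
package choice — it is the simplest recovery law characterized by a time
constant and mobile fraction; diffusion-equation (Soumpasis-type) models and
acquisition-bleaching reference correction (available but off by default)
are deliberately minimal because the upstream normalization protocol is
unreported and no published FRAP value is targeted.  A mobile fraction
fitting above 1 is clipped with a warning.

## Precision estimation

Repeated localizations of one fluorophore's on-period ("blinking events")
are grouped by the tracking linker (radius 100 nm, gap ≤ 1 frame by
default), and the per-axis precision is the pooled within-event standard
deviation over events with ≥ 2 members.  The estimator is translation
invariant and returns the frame of reference with the numbers.  The grouping
radius must comfortably exceed the 3D event spread (≈ √2·‖σ‖); simulations
at realistic precisions use 300 nm.

## Problem sizes and numerical choices

The bundled desk-scale study (`llstorm.pipeline.study_conditions`) runs the
full scanned-acquisition pipeline at a reduced scale chosen once for
single-CPU execution: per-membrane emitter densities 24/24/12 µm⁻²
(apical/interface/basal), mean on-time 1.5 frames, activation 10⁻³ per
excitable frame, 345 frames/stack × 30 stacks at 100 nm scan step
(~15,000 localizations, a few minutes).  Two properties of the full-scale
acquisition are deliberately preserved: per-frame spot density stays sparse
(localizations accumulate over many stacks, keeping PSF overlap at the
edge-on cell–cell wall rare), and window count statistics stay near Poisson
(short on-times avoid over-dispersed multi-frame bursts at one position).
Frames are rendered lazily during localization, so memory stays at one frame
regardless of acquisition length.  Monte-Carlo tests elsewhere use 200–400
trajectories, 10⁴–2×10⁴ blinking events, and 10–20 seed replicates; all
stochastic outputs are bit-reproducible given (seed, config).

Optimizer settings: spot fits run L-BFGS-B with analytic gradients
(ftol 1e-14, ≤ 200 iterations, width bounds 0.4–13 px); FRAP fits use
bounded Levenberg-Marquardt/TRF with data-driven initial values.  Degenerate
inputs (all-zero ROIs, NaN pixels, empty tables, singleton events, masks
smaller than one window) raise errors naming the offending quantity rather
than returning silent defaults.

## Known limitations

- The elliptical-Gaussian PSF underestimates localization accuracy
  achievable with experimental PSF models, particularly at |z| > ~500 nm.
- Densities at inclined membranes are per projected area (no 1/cos θ
  correction), matching the upstream convention but biasing steep regions.
- The linker is nearsighted (per frame pair); it does not globally optimize
  across frames and has no motion model.
- No drift correction, chromatic registration, multi-emitter fitting, or
  sCMOS per-pixel calibration.
- The rotated-frame precision estimate is the estimator applied to rotated
  coordinates; it is not claimed to reproduce any particular published
  rotated-frame value (the original estimator is unpublished).
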