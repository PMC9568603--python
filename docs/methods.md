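# Methods

This note documents the models, numerical choices and limitations behind
`beadcycle`. Units throughout: µm, s, pN, Hz, K; k_B = 1.380649×10⁻⁵
pN·µm/K; temperature default 303.15 K (30 °C assay conditions); medium
viscosity default 10⁻³ pN·s/µm² (≡ 10⁻³ Pa·s, water-like growth medium).

## Physical model of the trapped bead

The bead is an overdamped sphere in a harmonic optical trap:

    γ dx/dt = −κ (x − c) + F_drive(t, x) + √(2 k_B T γ) ξ(t)

with Stokes drag γ = 6πηa and per-axis stiffness κ. The closed-form
stationary statistics (variance k_BT/κ per axis, relaxation time γ/κ,
corner frequency κ/2πγ, diffusivity k_BT/γ) serve as the independent
oracle for both the simulator and the calibration estimators.

**Integration.** Driving-free segments (Brownian motion, pilus release)
are sampled with the *exact* discretization of the Ornstein–Uhlenbeck
process — an AR(1) recursion with factor exp(−Δt/τ) — which is unbiased at
any step size and vectorizes. Only the nonlinear gyration driving needs a
fine-step Euler–Maruyama integration (default step min(1 ms,
1/(10·frame rate)), always ≲ τ/10 for the shipped trap settings; a coarser
step triggers a warning). Schedule segment boundaries are rounded to the
frame grid (≤ half a frame interval) so planted and recovered intervals
share one clock.

**Gyration driving.** The rotating flagellum is modeled as a tangential
force of magnitude F_rot (with respect to the instantaneous radius from the
trap centre, CCW positive) plus an outward radial force F_trans. The
noise-free steady orbit then satisfies two exact balances: κ·r* = F_trans
and γ·ω·r* = F_rot. This makes force inference by drag balance exact by
construction and ties the two driving knobs to observables; when a target
orbit frequency is requested instead of a force, F_rot is derived as
2πf·γ·F_trans/κ. The long-axis-rotation stage (after septum softening)
is the same driving with F_rot halved (configurable), reflecting the slowed
gyration of the predivisional cell.

**Trap stiffness default.** The packaged default κ = 2 pN/µm is chosen so
that the default maximal translational force of 1.2 pN corresponds to a
0.6 µm displacement (the µm-scale bead excursions typical of such
recordings), and,
with F_rot = 0.3 pN and 3 µm-bead Stokes drag, yields a gyration frequency
of ~2.8 Hz — the seconds-per-revolution regime such assays operate in. Calibration-oriented tests additionally use a soft
κ = 0.05 pN/µm trap where thermal excursions are large.

**Pilus cycles.** A pilus attachment cycle is modeled kinematically: upon
attachment the tether prescribes the bead position (the pilus force
dominates trap and flagellum), dragging it at the retraction speed
(default 0.1 µm/s) along a fixed anchor bearing until the hold displacement
(default 0.5 µm) is reached, holding with localization-scale jitter
(10 nm), then releasing — the tether vanishes and the bead relaxes into the
trap as an exact OU path with time constant γ/κ (~14 ms at the default κ),
so the release speed exceeds retraction by well over the required factor of
10. No pilus force–velocity relation is modeled: the assay observes
displacement phenomenology only, and segmentation needs nothing more.
Retraction is capped at 45% of the drawn cycle duration so short cycles
remain well-formed; the anchor bearing is drawn within ±60° of the outward
radial direction at attachment (pili drag the bead out of the trap).

**Free swimmer.** Run-reverse motility: alternating push/pull sequences
with exponential durations (means 2.2 s / 1.2 s), per-sequence speeds, a
body axis undergoing rotational diffusion (0.1 rad²/s default) that is
continuous across reversals (the motion flips, the cell does not turn), and
positional diffusion using an effective assembly radius of 1.5 µm (bead
plus cell body, not the bare 1 µm bead). Quasi-2D: no z-motion anywhere in
the package, mirroring the thin-chamber, hydrodynamically-trapped swimming
of the assay; the ~10% force underestimation that ignoring z causes for
real data is a documented limitation, not modeled.

**Pole tracks.** The flagellated pole of a surface-attached predivisional
cell is a quadrature pair x = A cos(2πft+φ), y = ±A sin(2πft+φ)
(+ = CCW in image coordinates with y up — the sign convention used
throughout), with per-interval frequency and direction, preceded optionally
by sub-Hz large-amplitude bending along a fixed axis and followed by
ballistic drift after release. Gaussian localization noise is added.
Frequencies above a quarter of the frame rate are rejected (aliasing).

## Planted distributions: moment-matched truncated normals

Every "mean ± SD" quantity the generator plants is drawn from a truncated
normal on its physical range (a stated range where one is known, otherwise a
positivity or detection-floor bound). Crucially the generator solves for
the *underlying* normal parameters such that the **truncated** distribution
reproduces the target mean exactly and the SD as closely as the family
allows: measured assay statistics describe the observed, bounded samples,
and naive "truncate after the fact" sampling would shift some planted means
by 10–20% (e.g. the CW pole frequency, mean 29.9 SD 25.6 truncated at
1 Hz). Two default SDs are infeasible on their stated ranges (activity
duration: SD 57.3 s on [40, 180] s; rotation stage: SD 7.6 s on [2, 17] s —
no distribution on those intervals with those means attains those SDs);
there the solver preserves the mean exactly, which is the quantity all
downstream comparisons use, and accepts the maximal attainable SD.

Swim speed draws are truncated below at the 2 µm/s detection floor: a
measured "sequence speed" is by definition above the floor of the assay,
and sub-floor planted sequences would be invisible to any classifier.

## Inference stages

**Tracking.** Coarse detection by difference-of-Gaussians bandpass and
maximum (accepted at ≥ 4 noise SDs, else an explicit "lost" result);
sub-pixel refinement by an iterative Gaussian-masked centroid on the raw
window (mask width = spot σ, re-centred each iteration). For a symmetric
spot the fixed point is unbiased, and at SNR 10 the per-axis RMSE reaches
the Cramér–Rao limit for additive Gaussian noise, σ_noise/amplitude·√(2/π)
≈ 0.08 px — no Gaussian fitting needed at the precision the analysis
requires. Lost gaps up to 5 frames are linearly interpolated and flagged;
longer gaps terminate the track. Pixel convention: pixel centres at integer
coordinates, origin at the top-left pixel centre, x = column, y = row; the
renderer and tracker share this orientation, so µm↔px conversion is a pure
scale plus offset (the stack records the µm position of pixel (0,0)).

**Calibration.** Equipartition with per-axis mean subtraction; CIs from a
moving-block bootstrap with block length 10× the relaxation time estimated
from the ACF (OU samples are autocorrelated; an i.i.d. bootstrap would
understate the CI). The PSD route fits the Lorentzian to Welch spectra
only below fs/8: the sampled spectrum folds (aliases) the Lorentzian tail
back below Nyquist, and fitting the full band biases f_c upward by tens of
percent. Camera blur/aliasing corrections for real detectors are out of
scope. Estimates on < 100 samples are refused; < 10⁴ samples are flagged.

**Force inference.** F_rot = γ_eff · ⟨|ω|⟩ · ⟨r⟩ over gyration frames, ω
from the Savitzky–Golay derivative (5-frame window) of the unwrapped polar
angle. γ_eff defaults to the bead-only Stokes drag and is therefore a
declared lower bound — the attached cell adds unmodeled drag, which is why
recovered forces are compared to planted simulator forces, never to an
absolute real-world F_rot. F_trans_max = κ × the 95th percentile of the
radial displacement averaged over 0.5 s: the maximal translational force is
a sustained plateau, and the raw maximum of a noisy series is an
extreme-value statistic biased upward ~10% at 10³–10⁴ frames; quantile 1.0
with zero smoothing recovers the raw maximum (and restores exact
monotonicity under track concatenation).

**Segmentation.** Features on 0.5 s windows with 50% overlap (positions
Savitzky–Golay smoothed before path-length and radial quantities so noise
does not dominate the path length): mean |angular velocity|, net signed
angle, sign consistency, radial mean/velocity/monotonicity, positional
variance, directedness = net displacement / path length. Rule cascade:

* *pilus attached* — radial mean > r_thresh (3√(k_BT/κ)) AND (directed:
  directedness > 0.7, OR retracting: outward radial velocity in
  [0.03, 1] µm/s sustained (monotone fraction > 0.7) and not rotating, OR
  holding: positional variance below the thermal level k_BT/κ while
  off-centre);
* *gyration* — |net angle| > π/2 per window with consistent sign AND
  radial mean above the orbit floor (angular diffusion near the centre
  produces large apparent net angles without a real orbit);
* *long-axis rotation* — gyration-signature windows whose |ω| falls below
  0.75× the track's own median gyration |ω| (meaningful only when both
  stages are present, as in the pre-separation timeline);
* otherwise *Brownian*.

Ties go to the pilus (attachment arrests gyration). Frames take the label
of the nearest window centre; runs shorter than 0.4 s merge into their
longer neighbour (hysteresis). Onset of flagellar activity = start of the
first gyration interval; separation = the transition into the terminal
Brownian interval.

Pilus sub-phases: the attachment time is refined by walking back along the
monotone outward ramp (window classification fires only once the bead is
clearly displaced); the release end forward until the radius has relaxed to
the thermal floor or the fast inward run ends. The retract/hold boundary
uses a radial velocity averaged on the 0.5 s scale (the 0.1 µm/s retraction
sits below frame-to-frame noise), while release detection uses the
frame-rate velocity (the release is ~10³ times faster). Cycles without a
release before the track ends are flagged incomplete; intervals under
three windows are emitted with sub-phases unresolved. The reported
rotation-stage statistic is the per-track *total* long-axis time, robust to
a brief misclassified window splitting one physical stage.

**Swim classification.** Velocity per frame interval projected on the body
axis (simulator ground truth when available, else the sign-continuous
smoothed heading — in that mode directions are consistent up to a global
sign). Same-sign runs above the 2 µm/s floor become sequences; sub-floor
gaps < 0.5 s between same-sign runs are bridged; a single-frame sign island
below twice the floor is treated as a noise blip, not a reversal (genuine
reversals project at full swimming speed). Both the count fraction and the
time fraction of pushing are reported, since "fraction of sequences" is
ambiguous between the two readings.

**Rotation analysis.** Per 0.5 s window: zero-padded periodogram peak of
x(t) with parabolic interpolation (bias ≪ 0.5 Hz across 5–50 Hz at 200 Hz
sampling); direction from the sign of ⟨x·ẏ − y·ẋ⟩; windows whose peak is
< 6× the median power are unclassified. Adjacent windows with one
direction and frequencies within 20% merge; intervals supported by fewer
than two windows are dropped (single windows straddling a direction switch
carry mixed spectra); each interval's frequency is re-estimated over its
full span.

## Recovery experiments and problem sizes

Each experiment plants parameters through the generator and reports the
recovered quantity next to the planted per-run sample value and the
packaged population value; stochastic recovery is judged
estimator-to-planted-sample (same realization, tight), while
planted-to-default holds by construction of the moment-matched generator.
The acceptance script runs, per master seed: 800 swim sequences per
direction for speeds and 1500 for durations (20 Hz); 28 trapped tracks ×
15 pilus cycles for each flagellum condition (50 Hz); 600 pole cells with
4 alternating-direction rotation intervals each (200 Hz); 150
activity-lifetime tracks with the long-axis stage inserted before
separation. These sizes keep every Monte-Carlo standard error at 2–4% of
the target mean — small against the 5–10% recovery tolerances — and the
full run takes ~1 minute on one CPU. The test suite uses smaller instances
of the same experiments plus noiseless closed-form constructions.

## What the synthetic data do and do not show

The generator reproduces the *statistical structure* the inference assumes:
OU statistics of the trapped bead, crisp state signatures at the default
rates, durations and frequencies, camera-free Gaussian-spot
imaging. It omits: cell-body imaging and shape; hydrodynamic wall coupling
and flagellar filament mechanics; z-motion; camera blur and nonuniform
illumination; drift; multiple interacting cells per bead; any pilus
force–velocity relation. Passing recovery therefore validates the
*pipeline* — that the estimators return what was planted at realistic noise
— not the biological model itself; on real recordings the declared
lower-bound drag, the unmodeled blur and the hand-set segmentation
thresholds (validated only against this simulator) are the first things to
revisit.
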