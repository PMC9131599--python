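# Methods

`pedalemg` analyses agonist–antagonist co-contraction in pedaling surface
electromyography (sEMG) and simulates an auditory biofeedback system that
sonifies two of the recorded muscles. This note documents the models,
parameter choices, numerical decisions and known limitations.

## The measurement model

Four lower-limb muscles are recorded at 1000 Hz: vastus lateralis (VL, knee
extensor), semitendinosus (ST, knee flexor), rectus femoris (RF, hip
flexor/knee extensor) and biceps femoris long head (BF, hip extensor/knee
flexor). Pedal and crank-axis markers are captured at 100 Hz. The crank
angle θ is 0° with the pedal at the top dead center and increases in the
direction of rotation; one cycle runs from one top-dead-center passage to
the next. Trials are 90 s at 80 rpm, so a complete recording contains 120
cycles.

## Offline envelope chain

Each raw channel passes, in order: zero-phase 4th-order Butterworth
high-pass at 20 Hz (motion-artifact removal) → mean subtraction →
full-wave rectification → zero-phase 4th-order Butterworth low-pass at
15 Hz. "Zero-phase 4th-order" is implemented as a 4th-order design applied
forward and backward (`scipy.signal.filtfilt`), i.e. an 8th-order magnitude
response with no phase delay and no cutoff correction — the dominant
convention in biomechanics. Edge effects are handled by reflection padding
(`padtype="even"`, default pad length). Residual negative ripple after the
final low-pass is clipped to zero. Inputs shorter than ~0.1 s plus the
filter pad are rejected.

Each cycle is then linearly resampled onto 200 points at fractions
k/200, k = 0…199, of the cycle — a half-open grid, so the shared boundary
sample belongs to the next cycle. Linear interpolation is shape-preserving
and keeps non-negative data non-negative. Finally each muscle of each
participant is divided by its single peak over *all* cycles of *all*
conditions, so the global maximum per participant-muscle is exactly 1 and
relative amplitude differences between conditions survive normalization.

## Co-contraction index

For two normalized envelopes e₁, e₂ on the 200-point cycle base,

    COI = 2 · ∫ min(e₁, e₂) / (∫ e₁ + ∫ e₂) × 100  [%]

with the common area operationalized as the integral of the pointwise
minimum (Winter's convention). All integrals use the trapezoidal rule over
the **periodic closure** of the cycle grid: the point after sample 199 is
sample 0 of the next revolution, which is physically exact for a crank
cycle and, on a uniform unit grid, reduces the trapezoid to the plain sum
of grid values. Unit grid spacing is used throughout; the spacing cancels
in the ratio. The minimum is taken at grid points only — crossings of the
two piecewise-linear envelopes between grid points are ignored; property
tests bound this discretization effect (below 1% for envelopes of
physiological smoothness).

Two bases are exposed: `ensemble` (default) computes the COI of the two
ensemble-averaged waveforms, matching how cycle-normalized sEMG is
conventionally displayed; `per_cycle_mean` computes a COI per cycle and
averages. Both are reported per trial; the statistics stage consumes the
configured basis.

## Kinematics

The crank plane is the plane of maximal variance of the pedal-minus-axis
vector (SVD of the centered vectors), oriented by projecting the lab
vertical into the plane; the sign convention follows the direction of net
rotation. This avoids assuming lab axes beyond which coordinate is "up".
Cycle boundaries are upward crossings of 360° multiples of the unwrapped
angle, located by linear interpolation between the bracketing 100 Hz
frames (sub-frame precision matters because the sEMG runs at 1000 Hz);
partial leading/trailing cycles are discarded. A monotone envelope
(running maximum) of the angle guards crossing detection against
noise-induced local reversals.

A dead-center passage within 1° beyond the recorded angle range is snapped
to the recording edge. Rationale: with typical optical marker noise
(0.5 mm on a 170 mm crank ⇒ ~0.2° angle noise), a trial that starts and
ends exactly at the top dead center would otherwise gain or lose its
boundary crossing at random; 1° corresponds to ~2 ms at 80 rpm, far below
cycle-duration variability. Mid-cycle starts are unaffected and still
excluded as partial cycles. Cycle-bound times are mapped to sEMG samples
by nearest-sample index, with both clocks assumed synchronized at t = 0.

## Biofeedback simulation

The real-time leg is simulated sample-synchronously at the sEMG rate with
no latency model:

- **Causal envelope** — full-wave rectification followed by a trailing
  weighted moving average. Default: 100 ms window with linearly increasing
  weights (most recent sample weighted most), normalized to sum to 1 — a
  common low-latency sEMG smoother; a uniform window is available.
- **Threshold (5% rule)** — `threshold = rest + 0.05 · (pedaling_max −
  rest)`, from the mean causal-envelope level at rest and the maximum
  during ~1 min of calibration pedaling. The alternative reading
  (`0.05 · pedaling_max`, ignoring rest) is exposed as
  `threshold_rule="absolute"`.
- **Beep events** — maximal runs with envelope > threshold; gaps shorter
  than the 50 ms debounce are bridged and remaining events shorter than
  50 ms dropped, preventing audible chatter near the threshold
  (configurable, 0 disables).
- **Pitches** — VL 400 Hz, ST 800 Hz. Overlap between the two beep
  streams is the measure of the intersection of the event-interval unions;
  the fraction is relative to the shorter stream's total on-time.
- **Audio** — gated pure sines with 10 ms raised-cosine on/off ramps,
  summed and peak-normalized to 0.9 full scale; written as 16-bit PCM WAV
  at 44.1 kHz.

## Statistics

One-way within-subject ANOVA on the balanced participants × conditions COI
table: SS_total = SS_subjects + SS_conditions + SS_error,
F = MS_cond / MS_err with df (k−1, (n−1)(k−1)), partial
η² = SS_cond/(SS_cond + SS_err). The sphericity-assumed p is primary;
the Greenhouse–Geisser ε (from the double-centered condition covariance,
clamped to [1/(k−1), 1]) and the GG-corrected p are always reported
alongside. Missing cells are an error — no imputation. Normality is
screened per condition with the Shapiro–Wilk test (scipy implementation);
α = 0.05 is reported in outputs, not hard-coded into return values. The
implementation is cross-checked against `pingouin.rm_anova` in the test
suite.

## Synthetic data

No raw recordings are publicly available, so the generator is a
first-class, tested module producing data with known ground truth.

- **Activation templates** — per muscle, a sum of raised-cosine bursts
  (center, full-support width, amplitude) on the crank-angle circle,
  wrapping across 0°/360°. Defaults encode the qualitative pedaling
  pattern: VL centered 350° (width 90°) around the top dead center; ST
  bursts at 90° (width 180°) and 315° (width 90°); RF active from ~190°
  through the top to ~90° via bursts at 240° (width 100°, amp 0.8) and 0°
  (width 180°); BF at 90° (width 180°). Exact burst shapes are a
  documented free choice validated against the qualitative description;
  the phrase "activated around the top bottom center" in the source
  description of VL is internally inconsistent and is resolved as *top*
  dead center, consistent with knee-extensor function.
- **sEMG surrogate** — `x(t) = (floor + snr·floor·T(θ(t))) · w(t)` with
  `w` zero-mean unit-variance Gaussian noise band-limited to 20–450 Hz.
  This is the standard amplitude-modulated-noise surrogate: its rectified,
  smoothed trace tracks `floor·(1 + snr·T)`. Defaults: floor 0.01 mV,
  snr 10. Consequently the analytic expectation of the pipeline-recovered
  COI is the COI of the *peak-normalized pedestal envelopes*
  `(1 + snr·T)/max(1 + snr·T)` — recorded per trial in the ground truth —
  not the bare template COI.
- **Study design** — 13 participants × conditions (NFB, VLFB, STFB,
  VL-STFB) × 90 s at 80 rpm; sEMG 1000 Hz, markers 100 Hz. Signals span
  [0, duration] inclusive (n = duration·fs + 1 samples) so the final
  dead-center crossing of a whole number of revolutions is recorded.
  Between-participant variability: burst centers jittered with σ = 5° and
  a per-participant lognormal amplitude gain (σ = 0.2) per muscle, shared
  across that participant's conditions — enough to make between-subject
  COI variance non-degenerate without changing the designed means. A
  5 s rest recording (noise floor only) per participant supports threshold
  calibration. `condition_overlap_shift` translates the ST burst centers
  in chosen conditions (positive values move ST activity toward the VL
  burst, raising the designed VL–ST overlap), giving a controllable,
  analytically known condition effect; the default is 0 for all conditions
  (null design).
- **Markers** — pedal on a 0.17 m circle about the axis at constant
  angular velocity, starting at the top dead center, with 0.5 mm isotropic
  Gaussian jitter (typical optical-capture noise).
- **Seeding** — every stream's seed derives deterministically from
  `master_seed` via `numpy.random.SeedSequence(master_seed,
  spawn_key=(participant, condition, stream))`; equal configuration gives
  a bitwise-identical dataset.

What the surrogate does *not* emulate: motor-unit physiology, fatigue,
electrode artifacts beyond stationarity, workload/heart-rate dynamics, and
any behavioural response to the feedback (conditions differ only by their
designed templates and noise seeds). Passing recovery tests therefore
demonstrates correctness of the signal-processing and statistical chain,
not that the feedback intervention itself alters human co-contraction.

## Problem sizes in tests and the acceptance script

Unit and pipeline tests use compact studies (2–3 participants, 10–30 s) —
enough for ≥ 13 cycles per trial and stable envelopes. Parameter-recovery
checks run the full design (13 × 4 × 90 s, snr 10): every trial must yield
exactly 120 cycles and an ensemble COI within ±3 points of its designed
value. The Monte-Carlo type-I-error check uses 1000 replicates of a
13 × 4 exchangeable-normal null at α = 0.05 (expected rejection rate in
[0.03, 0.07]).

## Known limitations

- The crank-plane recovery needs non-degenerate rotation; a horizontal
  crank plane (vertical axis orthogonal projection vanishing) is rejected.
- Per-cycle COI at low SNR is noisier than the ensemble basis; the ±3-point
  recovery contract is stated for the ensemble basis.
- The GG-corrected p uses the standard ε-scaled F reference distribution;
  no Huynh–Feldt correction is provided.
- The biofeedback simulation is open-loop: beeps are derived from the
  signals but do not feed back into them.
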