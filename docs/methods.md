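# Methods

This note documents the models and procedures implemented in `vrgaze`, the
parameter defaults and why they were chosen, the simulator the validation
relies on, and the numerical decisions that were genuinely open.

## Coordinate conventions and data model

Coordinates are an arbitrary 3D Cartesian frame; nothing in the geometry
depends on handedness.  The vertical axis is y by default (the convention of
the common VR engines) and is configurable where it matters (head-frame
construction, the simulator's ground plane).  A gaze sample carries the eye
origin, the allocentric ("world") viewing direction, head position and
direction, the ray-cast hit point and hit-object id, a validity flag, and a
provenance flag (`measured`, `interpolated`, `timestamp_interpolated`).
Absent hit points are NaN/`None`, never numeric sentinels.  Engine-exported
"normalized" directions are not exactly unit length, so they are
renormalised offline; zero-norm directions mark the sample invalid.

## Translation-corrected angular velocity

For consecutive samples at `t1 < t2`, the hit-point shift
`v = hit(t2) − hit(t1)` is reduced to its component orthogonal to the unit
viewing direction `ê(t1)` (orthogonal rejection `v⊥ = v − ⟨v,ê⟩ê`), and

    w(t1) = atan2(‖v⊥‖, ‖origin(t1) − hit(t1)‖) · (180/π) / (t2 − t1).

Properties this buys: `w ≡ 0` for any observer path with a fixed hit point
(exact, used as an invariance test); a pure translation with a frozen
allocentric direction yields `w > 0`; for a static observer and matched
hit-point distances, `w·Δt` agrees with the direct inter-vector angle to
within 5% up to 10° displacements (the small-chord approximation; verified
against an arccos-dot oracle).  Both the viewing direction and the distance
term are taken at `t1`.  The velocity is timestamped at `t1`; the series is
one element shorter than the recording.

The construction deliberately measures only the *transverse* angular change:
a gaze jump mostly along the depth axis (e.g., from a distant facade to a
nearby object on almost the same ray) produces little transverse hit-point
shift and is under-estimated.  This is a known bias of the hit-point-domain
correction, visible in the validation as a small number of missed
depth-dominated saccades.

Saccade amplitude reuses the construction between the centroids (mean hit
points) of the two flanking gaze events, evaluated from the saccade-onset
viewpoint, without dividing by time.  The onset viewpoint (rather than a
midpoint) was an open choice; it matches the indexing of the velocity.

## Preprocessing

Order: validity handling first, then filtering.

* Invalid runs **longer than 20 ms** (blinks, tracking loss) are padded by
  **23 ms** on each side — the samples flanking a blink are unreliable.
  Run duration is measured as the run's timestamp span plus one nominal
  frame period, so a k-sample run counts as ~k frames.
* Invalid runs **shorter than 250 ms** are then linearly interpolated
  (positions, directions, hit points; directions renormalised afterwards).
  The hit-object identity is categorical and stays absent.  Runs touching
  the recording edge are never extrapolated.  Both thresholds are read as
  strict inequalities and are configurable.  Interpolated data are retained
  for kinematics but interpolated *timestamps* (inserted for dropped
  frames) can never host an event onset used for EEG.
* Observer positions and hit points are **5-point median filtered**
  (window shrinking to 3 points, then passthrough, at the edges), which
  removes single outlying samples without smearing saccade edges the way a
  moving average would.  Head directions are not filtered (open point;
  decided against, since they only feed diagnostic measures), and viewing
  directions are used raw after renormalisation.

Velocities are clipped at **1000 °/s** (biologically impossible values) and
Savitzky–Golay smoothed.  The smoothing window is **5 samples, order 2**,
both configurable: at 90 Hz a seconds-long window would flatten every
saccade, and a 3-sample window at order 2 degenerates to a passthrough, so 5
is the shortest non-degenerate choice.  Smoothing runs per contiguous valid
run (invalid intervals never enter a window; runs shorter than the window
pass through) and the output is clamped to [0, clip] because an order-2 fit
overshoots at sharp peaks.

## Segmentation and classification

The adaptive threshold is `median + k·MAD` of the velocities in scope
(`k = 3` by default; fewer than 3 values fall back to the recording-wide
threshold).  Thresholding the whole recording at once only finds the very
largest saccades, so two segmentations are provided:

* **data-driven** — maximal suprathreshold runs under the *global*
  threshold are scored by their summed velocity (the run sum, not the
  suprathreshold excess — an open reading, decided for the simpler one);
  the top `round(target_rate · duration)` runs each place one boundary at
  their peak-velocity sample (boundaries should bisect saccades, not
  fixations).  `target_rate` defaults to 2 Hz and is configurable.
* **fixed_10s** — boundaries every 10 s; the final partial segment is kept.

Within each segment, intervals with velocity strictly above the segment
threshold are saccade, the rest gaze; invalid intervals are invalid.

**Sample attribution.** Interval labels describe the motion *between* two
samples, so building events requires attributing them to samples.  Interior
samples flanked by same-label intervals take that label; at transitions the
shared sample is stationary on one side and goes to the gaze if either
neighbour is a gaze, else to the later interval.  Consequently a sample
counts as in-flight only when both its arrival and departure intervals are
suprathreshold.  This keeps the last stationary sample before a saccade and
the landing sample out of it, which measurably improves sample-level
agreement with simulated truth at 90 Hz; gaze onsets (the EEG-critical
boundary) are unaffected.

**Event repair.** Saccades < 20 ms and gazes < 40 ms are absorbed into the
immediately preceding event (which keeps its kind); a too-short leading
event is absorbed forward.  Absorption can create same-kind adjacencies, so
fusion and absorption iterate to a fixed point (each step reduces the event
count, so termination is guaranteed).  Too-long events are flagged
per kind at `median + 3.5·MAD` of the durations pooled across all provided
sequences (one-sided: only too-long).  A degenerate MAD of zero flags
nothing when all durations are equal (up to float tolerance) and anything
strictly above the median otherwise.  Each gaze is assigned the modal
hit-object id among its samples, ties broken by earliest occurrence.
Finally, events containing any still-invalid sample are relabelled invalid,
and gaze events whose onset sits on an inserted timestamp are marked
unusable as EEG events.

The pipeline is deterministic: identical input and configuration produce
byte-identical event tables.

## Clock synchronisation

Inter-sample gaps exceeding 1.5 nominal periods (the margin separating
frame-time jitter from true drops at 90 Hz) are filled with evenly spaced
inserted timestamps flagged `timestamp_interpolated`.  The affine map to the
EEG clock subtracts the first EEG timestamp and spreads the signed
difference of the two stream durations linearly over the eye-tracking span
(`endpoint` method).  The drift is treated as *signed* — a fast or slow
engine clock both correct properly — although only its magnitude is
typically reported.  A `least_squares` variant fits the affine map through
the endpoints plus optional shared marker pairs, for when the endpoints
themselves are noisy.  Onsets map to EEG sample indices by nearest-sample
rounding with ties to even (unbiased).  On exactly linear injected drift the
endpoint estimate is exact to float precision; with frame-time jitter of
0.9 ms the residual misalignment stays well below half an EEG sample.

## Fixation-onset EEG

Epoch windows are half-open in samples, `[round((t+w0)·rate),
round((t+w1)·rate))`, so sample counts are unambiguous; onsets whose window
leaves the matrix are dropped and counted.  The fERP is the plain trial
mean over −200..500 ms with no baseline correction — a continuous stream of
alternating gazes and saccades offers no neutral baseline; the upstream
0.5-Hz high-pass (assumed done, outside this package's scope along with
channel rejection/ICA) plays that role.

The fERSP uses complex Morlet wavelets with a fixed **3 cycles** at every
frequency (2–45 Hz, 0.5-Hz steps), favouring time resolution, on
−875..1175 ms epochs; the display window −500..800 ms keeps at least half a
wavelet of buffer at 2 Hz.  Wavelets are truncated at ±3σ of their Gaussian
envelope and amplitude-normalised (L1), so a sinusoid's power peaks exactly
at its own frequency bin; white noise then passes power proportional to the
wavelet bandwidth (~f), which cancels in the per-frequency dB baseline
`10·log10(P(f,t) / mean_t P(f, baseline))`, computed on trial-averaged
power (per-trial division is unstable) over −500..−200 ms — a window placed
before the saccade leading into the gaze.

The shift-correlation analysis re-extracts single trials at onsets shifted
by −1/0/+1 eye-tracking samples (±11 ms at 90 Hz) and correlates each with
the unshifted average — the ERP time course, or the trial-averaged power
plane over −200..500 ms flattened across frequencies and times (the
frequency handling is a free choice; vectorising the whole plane is the
natural one).  Data are high-pass filtered at 5 Hz first (zero-phase
windowed-sinc FIR, Hamming window, transition band 25% of the cutoff), on
both the trials and the average, since slow drifts are not the target of
the comparison.  On simulated evoked data the ERP median correlation peaks
strictly at zero shift while the ERSP medians are nearly shift-invariant —
the time-resolution of a 3-cycle wavelet (~300 ms at 10 Hz) dwarfs an 11-ms
jitter — reproducing the contrast that makes ERSPs attractive for
free-viewing designs.

## The simulator

The generator emulates the statistical structure of a free-exploration VR
recording on a simple scene (ground plane, eight 6–8-unit "house" boxes at
radius 15, four benches, a 6×6-unit walkable centre):

| parameter | default | rationale |
|---|---|---|
| sampling rate | 90 Hz, jitter σ 0.9 ms | engine frame rate; typical frame-time spread |
| fixation durations | gamma, mean 180 ms, shape 4 | matches gaze-duration medians of free-viewing VR recordings |
| saccade amplitudes | log-normal, median 10°, σ 0.5 | free exploration favours large gaze shifts |
| main sequence | duration = 2.2·A + 21 ms | any monotone law suffices for the r-based checks |
| saccade profile | raised-cosine velocity | smooth, symmetric, peaked; no physiological claim |
| head translation | bounded random walk, 0.1 units·s^-1/2 | small walking-like displacements |
| direction noise | 0.5° per tangent axis (noisy runs) | upper range of consumer VR eye-tracker precision |
| blinks | 3/min, gamma mean 150 ms | typical blink statistics |
| frame drops | p = 0.005 | "low number of frame drops" regime |
| EEG | 512 Hz, 1/f noise σ 5 µV, Gaussian evoked at 100 ms (σ 15 ms), 10-Hz oscillation, post-onset gain 0.5 in 150–400 ms | textbook fERP/fERSP phenomenology |
| clock drift | 53 ms per recording | a realistic engine-vs-amplifier drift magnitude |

Fixations hold a *world-fixed* target point, so the translation-corrected
velocity is exactly zero within fixations however the head moves — which is
what makes the simulator a sharp oracle for the geometry.  Saccades rotate
the gaze between targets with the raised-cosine profile; per-sample rays
are cast against the scene.  Corruption (direction noise with re-ray-cast
hit points, blinks, frame drops) and EEG rendering (template at each true
gaze onset, oscillation envelope, 1/f background, linearly drifted clock)
are separate stages.  Everything is deterministic under the configured
seed.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: post-saccadic oscillations, vergence/binocular
depth, smooth pursuit against moving objects, eye-tracker-specific error
fields, EEG artifacts (muscle, eye movement, channel noise), and overlap
correction of successive fixation responses.  Sample-level agreement
figures on simulation are upper bounds on real-data performance.

## Validation experiments (scripts/acceptance.py)

All figures are recomputed at run time from fresh simulations seeded by
`--seed`: translation invariance (1000 random paths; exact zero), the
static-observer geometry oracle (10 000 cases; ≤5% relative error), full
recovery on 10-minute recordings (sample agreement over
{gaze, saccade, invalid} and median gaze-onset error, noise-free and with
0.5° noise + 3 blinks/min + frame drops), segmentation boundary counts
(2 Hz and 10-s rules), recovery of a 53-ms drift over 30 minutes (residual
vs half an EEG sample), fERP template recovery at SNR 0.2
(RMS-over-epoch definition) with ~500 non-overlapping trials, the Morlet
sinusoid peak, dB stationarity (~0 dB for a stationary process), the
shift-correlation pattern, and byte-level determinism.  Agreement is scored
on the classification proper (merge repair included, too-long-outlier
relabelling excluded): ground truth has no notion of "too long", and
near-cutoff events flip arbitrarily between otherwise matched
distributions.  Problem sizes (10-minute classification runs, 30-minute
drift runs, 120–560-second EEG runs) were chosen as the smallest that make
the statistical checks stable.

## Known limitations

* Event boundaries are frame-quantized; sub-sample onset refinement is not
  attempted, so onset errors of up to half a frame (~5.6 ms) are intrinsic.
* Depth-dominated gaze shifts are under-estimated by the transverse
  velocity (see above) and can be missed entirely at low amplitudes.
* The 2-Hz data-driven boundary target is a configurable convention; on
  very quiet recordings fewer suprathreshold runs than the target exist and
  all of them are used.
* Smooth pursuit is not separated from fixation ("gaze" pools both), and
  no overlap correction is applied to successive fixation responses.
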