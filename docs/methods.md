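# Methods

`windcompass` pairs three synthetic-data generators with the analysis
chain used to characterize how *Drosophila* central-complex columnar
neurons encode airflow direction and how silencing them changes
closed-loop flight behavior. Every analysis stage can therefore be tested
against generator ground truth without any recorded data.

## Angle conventions

All angles are degrees on (−180, 180], fly-centered: 0° directly in front,
+90° ipsilateral to the recorded neuron (or, in behavior, to the right),
180° behind, −90° contralateral. In the flight arena the airflow source
sits at 0° in the world frame, so an orientation of 180° is downwind. The
"toward the source" quadrant is [−45°, +45°) (half-open at +45° so a
sample is never counted twice; immaterial for continuous data).

## Electrophysiology generator (`synthetic_ephys`)

Each 12 s trial is 4 s baseline, 4 s stimulus, 4 s post-stimulus at
10 kHz, with a 500 ms, −2 pA current injection at the start of the
baseline for input-resistance tracking. Sessions are block-pseudorandom:
every (direction, condition) pair appears once per block before any pair
repeats. The two standard designs are the survey (4 directions × 5
conditions × 4 repetitions = 80 trials) and the eight-direction
airflow-only design (8 × 1 × 5 = 40 trials), with a 9 s inter-trial
interval.

The neuron model is phenomenological, not conductance-based:

- **Tuning** is a circular Gaussian (von-Mises-shaped) bump of the
  stimulus direction, peak 1 at `pref_dir`. `tuning_width` is the
  half-width at half maximum (the concentration is
  κ = ln 2 / (1 − cos w)). `inhib_frac` > 0 shifts the bump down so the
  anti-preferred response is negative: spiking floors at zero while the
  membrane potential hyperpolarizes, emulating active inhibition by
  contralateral airflow.
- **Modality combination.** The airflow and stripe responses have
  amplitudes `a_air` and `a_stripe`; odor multiplies the airflow term by
  `a_odor_gain` (0.5 in the P-F1N3 preset emulates olfactory
  suppression). `integration_mode` combines the tuned terms by summation
  or by returning only the dominant modality's term. The stripe response
  peaks at `pref_dir + stripe_pref_offset`: visual and airflow
  preferences need not align in a cell, and modality-specific tuning is
  what makes summation distinguishable from dominance in the similarity
  analysis (with fully shared tuning the two unimodal timecourses are
  proportional and ρ_a = ρ_s in every mode).
- **Temporal profile** is tonic (flat) or transient (exponential decay
  with constant τ) over the stimulus.
- **Spiking** is an inhomogeneous Poisson process sampled per 0.1 ms tick
  with a 3 ms absolute refractory period; the per-sample hazard is
  dead-time-corrected (h = r / (1 − r·t_ref)) so the delivered rate
  equals the nominal rate in steady state. Spikes are rendered as 2 ms
  triangular depolarizations of amplitude `spike_amp` (40 mV default).
- **Membrane potential** adds a resting level, an optional sinusoidal
  baseline oscillation, Gaussian noise smoothed with a 2 ms kernel (and
  rescaled to keep the requested standard deviation), a subthreshold
  deflection proportional to the signed stimulus drive, and the Ohmic
  pulse response. Deterministic deflections (pulse edges, stimulus
  on/offset) are low-passed with a 10 ms kernel, standing in for the
  membrane time constant; without it the step edges leak through the
  40 Hz detection filter and masquerade as spikes.

Named presets (`make_neuron`) anchor resting potential, input resistance
and oscillation frequency to the measured cross-fly means per cell type
(P-F1N3: −18 mV, 6.21 GΩ, 4 Hz; P-F2N3: −22 mV, 4.86 GΩ, 2 Hz; P-EN2 and
P-F3N2d analogously), and set response amplitudes to the magnitudes those
cell types show: ventral P-FNs strongly airflow-tuned (25–30 spikes/s at
preferred), P-EN2 a moderate summator, P-F3N2d airflow-dominant.

What the generator does *not* emulate: spike-shape diversity across cell
types, bursting, adaptation, correlated (non-Poisson) spiking, slow
drift in recording quality, and movement artifacts. Passing tests
therefore certify the analysis chain's correctness and statistical
behavior on idealized recordings, not robustness to every pathology of
real patch data.

## Electrophysiology analysis (`ephys_core`, `integration`, `tuning`)

- **Spike detection**: second-order Butterworth high-pass at 40 Hz,
  applied forward-backward (zero phase, so spike times do not shift);
  spikes are upward threshold crossings, one per suprathreshold
  excursion. The default threshold is 5× the median absolute deviation
  of the filtered trace — a robust, self-scaling default standing in for
  per-cell manual thresholds — and can be overridden per recording.
- **PSTH**: spike trains binned at 1 kHz, convolved with a unit-area 1 s
  Hanning window, averaged across trials. Kernel mass falling outside
  the trial is folded back at the edges, so the integral of the PSTH
  equals the mean spike count exactly.
- **Windowed responses**: response-window mean minus baseline-window
  mean, with the 1 s windows ending 0.5 s before and starting 0.5 s
  after stimulus onset. Applicable to firing rate or membrane potential.
- **Input resistance**: ΔV/I from the test pulse. The pulse starts at
  t = 0, so the reference level is taken from the first-second samples
  outside the pulse (50 ms guard bands) rather than a pre-pulse segment;
  the steady state is the mean over the pulse's second half. An ongoing
  membrane oscillation biases the two windows differently — as it would
  in vivo — so input resistance is best read from tonic segments.
- **Baseline profile**: resting potential is the mode of the pooled
  baseline-Vm histogram (Freedman–Diaconis bins, 0.1 mV floor); the
  distribution width is the 5th–95th percentile range; the oscillation
  frequency is the Welch-periodogram peak in 1–10 Hz, accepted only if
  it is ≥ 4× the median in-band power, else "none". The band's low edge
  is 1 Hz so that the pulse-free 3 s baseline segment spans at least two
  periods; the cell types that oscillate do so at 2–4 Hz.
- **Strongest-direction response**: per direction, signed per-trial
  responses are averaged first and the absolute value taken afterwards
  (so strong inhibition can win, and cancelling trials cannot); the
  direction with the largest magnitude is selected.
- **Summation analysis**: per direction, predicted = mean stripe-alone +
  mean airflow-alone response; observed = mean multimodal response. The
  trimodal variant sums stripe-alone and airflow+odor means.
- **Similarity coefficients**: per condition, trial-mean PSTHs for the
  four survey directions are baseline-subtracted (the 1 s baseline
  window; a raw variant is available), truncated to seconds 4–12
  (stimulus + offset), concatenated in the fixed order (−90°, 0°, 90°,
  180°), and Pearson-correlated point by point: ρ_a against
  airflow-alone, ρ_s against stripe-alone. A zero-variance concatenation
  produces an explicitly flagged degenerate result (NaN), never a silent
  zero.
- **Mean tuning vector**: each direction contributes a vector with angle
  = direction and magnitude = signed mean response; the resultant's
  angle is the preferred direction and its length is normalized by
  Σ|r_i| to lie in [0, 1] (the normalization is this package's choice; a
  rectified variant is available but non-default). All-zero curves are
  flagged angle-undefined.
- **Response dynamics**: cumulative PSTH over the 4 s stimulus,
  normalized by its total; the time to half-max is the first crossing of
  0.5, linearly interpolated between samples. Zero or negative totals
  (inhibited cells) yield a flagged undefined profile.

## Closed-loop flight simulator (`closed_loop_sim`)

The control loop runs at 50 Hz: the difference in wingbeat angles (ΔWBA,
positive = rightward) is multiplied by a static gain of 0.04 and applied
as the orientation increment of that sample, capped at the motor's
maximum speed of 144°/s (2.88° per tick). The gain is defined as degrees
per unit ΔWBA *per control sample* — the loop multiplies once per tick —
which is the natural reading of a software loop at a fixed rate; only
the mapping from agent parameters to realistic ΔWBA magnitudes depends
on this choice. The motor cap applies in closed loop and during slips
alike (same motor).

Sessions are 20 s trials, one perturbation each, six types balanced and
block-shuffled (all six per block of six trials); ten repetitions each
give the standard 60-trial, 20-minute session. Perturbations: airflow
pauses of 2 s and 150 ms (the 150 ms pause is 8 samples at 50 Hz), and
open-loop slips of the source at full motor speed for 5 samples (14.4°)
or 22 samples (63.36°), left or right. During a slip the fly's input is
ignored; during a pause the loop stays closed but the agent switches
policy. The perturbation onset is placed 1 s into each trial so the 1 s
pre-stimulus analysis window of the first trial lies inside the session.

The fly agent is a phenomenological controller: ΔWBA = k · (wrapped
error from its preferred flow-relative orientation, downwind by default)
plus Gaussian motor noise, seen with a configurable latency; while the
airflow is off it applies a fixed-magnitude ΔWBA offset (`pause_bias`)
directed toward the source, emulating the brief toward-source turn at
flow pauses. No aerodynamics, wing kinematics, or vision are modeled.
Orientation is stored wrapped to (−180°, 180°] and is exactly
reconstructable from the ΔWBA series plus the schedule — the record
loader re-derives and checks it.

## Behavior metrics (`behavior_metrics`)

Orientation samples are unit vectors; their circular mean gives the
preferred orientation, the resultant length the fixation strength
(1 = perfect fixation, 0 = none), and the mass in [−45°, 45°) the
toward-fraction (0.25 under uniform orienting). Perturbation responses
are ΔWBA in a 6 s window (1 s pre, 5 s post onset; 301 samples); windows
truncated by the session edge are dropped and counted in a log message.
Slip responses are additionally integrated over the 5 s post-slip
(deg·s). The correction fraction divides the mean integrated response —
converted to orientation degrees through the closed-loop mapping
(× gain × 50 Hz), so numerator and denominator share units — by the
negative slip magnitude: 1 means the turn undid the slip exactly, 0 no
response, negative anti-corrective. The ratio-of-means form is the
default. Pause responses flip the sign of ΔWBA sample-by-sample so turns
toward the source are positive on either side of the arena; long-pause
integrals cover the 2 s pause. Histograms of integrated slip responses
use 20° bins centered on zero, with leftward-slip responses sign-flipped
before pooling, normalized to probabilities.

## Imaging generator and ΔF/F (`synthetic_imaging`, `imaging_dff`)

Each 47 s imaging trial at 5.0 frames/s is 5 s pre-stimulus, 10 s
airflow, 10 s airflow + odor, 10 s airflow, 12 s post. The green
(activity) channel is baseline × (1 + tuned response) × a(t) + noise and
the red (structural) channel is baseline × a(t) + noise, where a(t) is a
smooth multiplicative artifact shared by both channels (Gaussian-
smoothed noise, 2 s kernel) emulating slow Z-plane brain movement. The
tuned response uses the same circular-Gaussian family as the
electrophysiology generator, smoothed with a 1.5 s kernel standing in
for indicator dynamics; a flag mirrors the tuning across the midline
(the LAL-to-noduli input neurons are tuned opposite to ventral P-FNs),
and odor scales the response by `odor_gain` (1 by default: odor leaves
the response unchanged).

ΔF/F is per-channel (F − F̄)/F̄ with F̄ the mean over the trial's first
5 s; the corrected signal is ΔF/F_green − ΔF/F_red, which cancels the
shared artifact exactly up to additive noise — the cancellation residual
scales with the noise floor, not the artifact amplitude. No detrending
beyond the channel subtraction is applied. Epoch summaries average the
corrected signal per trial epoch and across the five repetition blocks
per direction. Pixel-level synthesis, motion correction, and ROI
segmentation are out of scope; the generator emits ROI traces directly.

## Statistics (`stats_report`)

Paired comparisons use the Wilcoxon signed-rank test (zero differences
discarded; exact null for ≤ 12 nonzero differences, continuity-corrected
normal approximation above — the two branches agree to ~0.015 at the
boundary), unpaired comparisons the Mann-Whitney U test (exact when
min(n) ≤ 8, n + m ≤ 16 and tie-free; tie-corrected approximation
otherwise), and distribution comparisons the two-sample
Kolmogorov-Smirnov test. All are two-sided by default with ties
mid-ranked. Families are Bonferroni-corrected (threshold α/m). Under the
null at n = 10 the rank tests reject at 0.04–0.05; the KS test is
conservative there (~0.015) because its exact small-sample null is
discrete — a property of the statistic, not of any implementation.

## Problem sizes and determinism

Every stochastic stage takes an explicit integer seed
(`numpy.random.default_rng`); identical inputs and seed give identical
outputs, byte for byte. The test suite and the acceptance script size
their simulations to what the properties require: spike-detection
fidelity over 100 trials, preferred-direction recovery over 20
eight-direction sessions, integration-mode recovery over 50 survey-style
sessions (4 repetitions, 3 conditions), rank-test calibration over
10,000 null draws, and single 60-trial behavior sessions.

## Known limitations

- The agent and neuron models are deliberately minimal; they reproduce
  the qualitative phenotypes (downwind fixation, corrective turns,
  toward-source pause responses, summation vs dominance) but no
  quantitative fly-to-fly variability.
- Correction fractions measured on real flies depend on wing-command
  dynamics during the open-loop slip; in the simulator a latency shorter
  than the slip duration lets unapplied wing commands inflate the
  integrated response, so "perfect correction = 1" holds exactly only
  for agents that react after the slip ends.
- The oscillation detector assumes a quasi-sinusoidal rhythm and a 3 s
  baseline segment; frequencies below 1 Hz are not searched.
- Single-channel noise in the imaging model is additive and white;
  photon (Poisson) statistics and bleaching trends are not modeled,
  though a red-only trend demonstrates how bleaching propagates into the
  corrected trace.
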