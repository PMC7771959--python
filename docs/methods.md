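# Methods

## The measurement being modeled

A Purkinje neuron's spiny dendrites are double labelled with a
voltage-sensitive dye (red channel; electrochromic, linear, ~2.1 mV per
% ΔF/F at 1020 nm excitation) and a calcium indicator (green channel).
Bidirectional linescans (512 pixels, 2 kHz line rate, 10.5 s) span the
dendritic width; a 100 ms air puff to the ipsilateral eye is delivered 5 s
into each recording. Climbing-fiber input evokes dendritic complex spikes
(DCS: bursts of 2–5 fast spikelets, 1–2 ms each, with a large calcium
transient); strong parallel-fiber input evokes occasional single dendritic
spikes (DS: a ramping depolarization ending in one spikelet with a small
calcium transient) and slow depolarizing / hyperpolarizing sub-threshold
envelopes. The analysis asks how these inputs interact: a linear
sub-threshold voltage→calcium coupling, a timing-dependent supralinear
enhancement when a DS follows a DCS, and an overall enhancement of
sensory-evoked DCS calcium transients.

## Pipeline

1. **Motion correction** — integer lateral (circular) shifts per line
   during the stimulus ± 200 ms, maximizing cross-correlation with the mean
   pre-stimulus spatial profile, searched within ±10 px, ties toward zero,
   boundary hits flagged. Both channels are shifted identically.
2. **Crosstalk removal** — one global least-squares scale of green onto red
   (estimated with an intercept so channel offsets do not bias the slope);
   `red − scale × green` is carried forward. The intercept is reported but
   not subtracted: removing a global constant would corrupt every pixel's
   ΔF/F baseline. The corrected channel is exactly uncorrelated with green.
3. **ΔF/F** — per pixel, relative to that pixel's mean over
   `[0, stimulus onset − 500 ms]`; this span excludes evoked activity and
   the separate 500 ms classification baseline. A non-positive baseline at
   a retained pixel is an error naming the pixel.
4. **Spatial averaging** — mean over pixels whose baseline brightness
   exceeds 50 % of the profile maximum (red channel defines the mask).
5. **Upsampling** — linear interpolation 2 → 10 kHz; original samples are
   preserved exactly.
6. **Filtering** — per use, recorded once per trace: 1 ms boxcar (voltage,
   detection), 10 ms (calcium gating; spike-free voltage), 5 ms (calcium
   peak measurement). Boxcars are centered moving averages with shrinking
   windows at the edges — no values are fabricated beyond the trace.

### Event detection and classification

Spikelets: local maxima of the 1 ms-filtered voltage with amplitude
≥ 3 SD and prominence ≥ 1 SD of the full trace (SD over the whole
recording, spikelets included — a literal reading; a MAD-based robust SD is
available behind a config switch), kept greedily in descending amplitude
with ≥ 2.5 ms separation. Groups are formed by transitive chaining of
≤ 10 ms gaps. A ≥ 2-spikelet group is a DCS if mean calcium (10 ms boxcar)
over the 20 ms after the first spikelet exceeds the 20 ms before it by
> 1 % ΔF/F. A singleton is a DS if the calcium gate holds **and** the mean
voltage over the 10 ms following the spikelet (window anchored just past
the spikelet's own width, so the spikelet does not contaminate its own
return-to-baseline test) stays below 1 SD. Groups failing their gates are
returned as rejected. Events are annotated with: evoked (onset inside the
stimulus window, offset inclusive), calcium peak (max of the 5 ms-filtered
trace over 200 ms after onset minus the 20 ms pre-onset mean — 200 ms
covers all observed times-to-peak), time-to-peak, and a multiple-DCS flag
(another DCS onset within the following 100 ms).

Spikelet removal replaces ±5 ms around each spikelet (overlapping windows
merged) with the mean of the 5 ms immediately preceding the window, then
applies a 10 ms boxcar. Response classification then uses ±2 SD thresholds
of the 500 ms pre-stimulus baseline within the stimulus window
(depolarizing / hyperpolarizing / both / no response); onset latency
requires the crossing to persist ≥ 5 ms (robust to single samples at
10 kHz), peak latency is the directional extremum.

### Statistics and coincidence analyses

PSTHs use 10 ms bins aligned to stimulus onset, rate = count /(trials ×
width). Outcome probabilities (none / DCS only / DS only / DCS+DS, in the
100 ms pre-stimulus and stimulus windows) carry bootstrap SDs from
resampling **trials** with replacement (n_boot = 1000, seeded). Location
contrasts use Welch's t-test and spikelet-count distributions a two-sample
Kolmogorov–Smirnov test. The voltage–calcium relation is an OLS fit of
trial-wise baseline-subtracted stimulus means on trials with no event
within ±300 ms of stimulus onset (Pearson r, p, pointwise 95 % CI).
DCS+DS pairs within 400 ms (no intervening DCS; lag positive when the DS
follows) are scored relative to same-spikelet-count unpaired single DCS,
pooled across the dataset for sample size (a per-neuron option exists);
the lag-sorted ratios are smoothed with an overlapping boxcar over 10
consecutive points and fitted with a two-term Gaussian by bounded nonlinear
least squares (centers within the observed lag range ± 50 ms, widths
> 1 ms, amplitudes unconstrained in sign, ten seeded restarts from the
primary/secondary extrema; non-convergence in all restarts is an error with
diagnostics). The pre-DCS analysis measures the mean spike-free voltage in
the 10 ms before single-DCS onsets per spikelet-count group (2–5),
predicts a calcium baseline increase via the fitted coupling slope, and
compares evoked calcium peaks against non-evoked mean + prediction.

## The synthetic generator

The generator is a forward model of the acquisition, not a biophysical
simulation. Defaults are the study conditions: DCS Poisson rates 1.05 Hz
baseline / 5.73 Hz stimulus, DS 0.13 / 1.24 Hz; spikelet-count distribution
(0.35, 0.35, 0.20, 0.10) over 2–5; raised-cosine spikelets (2 ms, 18 %
ΔF/F ≈ 38 mV — dendritic calcium-spikelet scale) with intra-burst gaps uniform in
[2.5, 6] ms so bursts resolve under the 2.5 ms detector yet chain under the
±10 ms rule; DS as a 20 ms, 1.5 % ramp ending in one spikelet; envelope
onsets/peaks 9/101 ms (depolarizing, exponential decay 80 ms) and
35/57 ms (hyperpolarizing), amplitudes drawn per trial (1.5 ± 0.4 and
1.1 ± 0.3 % ΔF/F, clipped at 1.0), mixed across trials at the observed
53/14/7/26 % proportions; the "both" envelope is a truncated depolarization
followed by a deeper hyperpolarization, reflecting its superposition
character. Calcium: a difference-of-exponentials kernel per spikelet (rise
15 ms, decay 400 ms, 4 % ΔF/F per DCS spikelet, so 2–5-spikelet bursts span
~8–20 % non-evoked and up to ~33 % evoked), a smaller fast kernel for the
DS spikelet (2.4 %, rise 3 ms, decay 50 ms — large enough that the 1 %
calcium gate detects DS without bias, small next to DCS transients),
linear coupling (slope 0.6 % per %) applied to the low-passed spike-free
voltage, a Gaussian pair-enhancement curve (×2.0 peak at +28 ms, width
30 ms) scaling the DCS kernel when a DS is nearby, and an evoked
multiplier ×1.66 on DCS with onsets inside the stimulus.

Baseline variability has two parts: a small Gaussian synaptic background
(SD 0.05 %, τ = 100 ms) and a **bounded pulsation artifact** on the voltage
channel (0.5 % sine at the ~10 Hz heart rate of an awake mouse, random
phase per trial, not coupled into calcium). The bounded component
dominates the classification baseline SD, which is what real traces require
for a ±2 SD threshold to be usable at all: a Gaussian-dominated baseline
would cross its own 2 SD level in a 100 ms window far too often for the
four response groups to be recoverable. Being periodic at 10 Hz, it
averages to zero over any 100 ms window, so stimulus-mean quantities (the
voltage–calcium relation) are unaffected.

DS are scheduled by rejection-resampling away from DCS burst windows
(±12 ms): a single spikelet inside a burst's chaining window is by
construction indistinguishable from a burst spikelet, so such ground truth
would be unrecoverable by any detector honoring the grouping rule.

The image forward model broadcasts the (line-rate-decimated) traces over
smooth periodic dendritic profiles — a cosine modulation for the membrane
dye, a sine for the cytosolic indicator. The quadrature choice reflects
the different compartments the two labels occupy and keeps the static
baselines from aliasing into the crosstalk regression (with co-linear
profiles the global red~green fit conflates baseline ratio and crosstalk,
and no regression-based estimate could recover the coefficient). Crosstalk
adds `c × green` to red; per-pixel Gaussian noise has SD `noise_sd_dff` %
of the local baseline; motion is integer circular shift per line during the
stimulus only (periodic profiles make exact recovery well defined); the
eyelid trace is a smooth closure transient peaking 128 ms after stimulus
onset at 100 frames/s. Trace-level simulation (`simulate_trial_traces`)
skips the image and adds white noise at the **spatially pooled** level
(0.05 % ≈ pixel noise / √mask size), matching what the image path delivers
after averaging; it is used for the large statistical cohorts.

### What the generator does not emulate

Photon-level shot noise (noise is Gaussian on the ΔF/F scale, matching the
SD-unit thresholds downstream); 2-D imaging and non-rigid motion;
bleaching; spatial heterogeneity across branches (signals are uniform
across the profile); somatic electrophysiology; biophysical channel
kinetics behind the enhancement curves. Passing recovery tests therefore
demonstrates the pipeline's correctness under the stated statistical
structure, not robustness to every artifact of real recordings.

## Benchmarks and problem sizes

The validation module runs the pipeline against ground truth at these
sizes, chosen to give stable statistics at interactive runtimes:
detection/classification fidelity on 20 default trials; rate recovery on
500 trials (baseline rates measured over the 4 s before stimulus onset);
timing-curve recovery on 20 independent sets of 400 pair points with ratio
noise SD 0.5 — the single-set peak-location estimator has SD ≈ 3 ms at
this noise level, so the benchmark reports the across-set mean; coupling
slopes {0.2, 0.6, 1.0} on 60 no-event trials each; null controls on a
250-trial spontaneous cohort (pair ratios) and a 300-trial stimulated
cohort (evoked vs linear sum) with all enhancement mechanisms disabled;
preprocessing oracles on short (3 s, 128 px) image trials.

## Numerical and design choices

* Upsampling before filtering preserves original samples exactly; the
  alternative order (time interpolation of the image before the corrections)
  agrees with ours within the noise floor on simulated data (tested).
* Detection SD over the full trace including spikelets; thresholds are
  therefore slightly conservative on event-rich trials.
* The calcium gate for a DCS anchors at the first spikelet of the burst.
* Bootstrap resampling unit is the trial.
* Tie-breaks: motion shifts toward zero; preferred-response ties toward
  depolarizing (logged).
* Degenerate inputs error loudly (empty masks, zero baseline SD, constant
  green channel warns with scale 0, flat eyelid traces), never silently.
* `run_all` aborts on stage failure with the stage name; downstream stages
  refuse inputs whose config hash mismatches unless forced.

## Known limitations

DS detection loses a small fraction (~10 %) of events whose 10 ms
return-to-baseline window collides with an unfavorable pulsation phase, and
DS riding the steep decay of a large evoked DCS transient can fail the
calcium gate; measured DS rates sit correspondingly a few percent below
injected rates (well within the benchmark tolerances). The relative
calcium peak of a DCS+DS pair includes the DS transient's own linear
contribution, so even a fully linear dendrite yields a mean ratio slightly
above 1; with the default small DS kernel this bias is within the null
control's resolution. Crosstalk identifiability relies on spatially
distinct channel baselines; for recordings where both labels share one
profile the global regression estimates baseline ratio plus crosstalk, as
any single-regressor method must.
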