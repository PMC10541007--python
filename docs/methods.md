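# Methods

This note records the models and procedures `songpeth` implements, the
defaults it ships and why, the numerical choices that were genuinely open,
and what the synthetic-data validation does and does not demonstrate.

## USV segmentation

The parser operates on a magnitude-squared STFT (Hann window, 512 samples,
hop 128; ≈ 0.51 ms × 488 Hz resolution at 250 kHz audio) restricted to the
ultrasonic band 20–125 kHz. Time resolution was chosen to resolve the 8 ms
duration and 16 ms gap rules with better than 10× margin; the band edges and
the 3×3 cleaning window are the standard recipe for mouse USV parsing.

**Binarization.** Each pixel is scored by a per-frequency-row robust
z-score of *log* power: (log P − row median) / (1.4826 · row MAD), detected
at z ≥ 4 (`detect_z`). The log scale matters: noise power in one STFT bin is
approximately exponential, whose raw-power upper tail makes any practical
robust-z threshold fire constantly, whereas log-power has a doubly
exponential upper tail and z = 4 yields a per-pixel false rate below 10⁻⁶ —
the empirical false-detection count on 60 s of signal-free noise is zero.
Row-wise statistics also whiten steady narrowband interference. Detected
pixels with no other detected pixel in the surrounding 3×3 window
(`min_neighbors = 1`) are removed as isolated noise.

**Syllables and songs.** Time bins with any detected pixel form runs; runs
separated by < 16 ms of silence merge *before* the ≥ 8 ms duration floor is
applied (otherwise two sub-8 ms fragments bridged by a 10 ms gap would
vanish despite forming one valid syllable). Both thresholds are inclusive on
the discretized grid: an exactly-8 ms run survives, an exactly-16 ms gap
splits, and a ≥ 10 s syllable-free gap starts a new song. Intervals are
half-open `[start, end)` seconds.

**Features.** A second, stricter threshold (`feature_z = 6`) is applied to
the syllable's spectrogram slab; the mean frequency is the unweighted mean
frequency of surviving pixels and the bandwidth is their frequency extent.
If no pixel survives the stricter threshold the features are reported
missing but the syllable is retained. One caveat found during validation:
at very high SNR (≫ 20 dB) the Hann window's own sidelobes pass the feature
threshold and inflate the measured bandwidth; at the 20 dB operating point
the bandwidth error stays within 2 frequency bins.

## Fiber photometry

Raw photodiode traces are anti-alias decimated to ~1 kHz (indicator
dynamics are far slower; acquisition rates of tens of kHz are a hardware
artifact). ΔF/F = (F − F₀)/F₀ with F₀ the 10th percentile of the whole
decimated session — a whole-session rather than rolling baseline, read
literally; an optional linear detrend (off by default) is available for
drifting sessions.

**Triggered average and permutation null.** The song-onset-triggered
average is the mean ΔF/F over windows [−pre, +post) around each usable
trigger (clipped windows are dropped and counted). The null redraws the
same number of triggers uniformly over the valid span `n_perm` times
(default 1000) and recomputes the triggered mean; per-timepoint null mean
± SD give the display bands, and significance is assessed with a single
max-statistic: p = (1 + #{null peak ≥ observed peak}) / (n_perm + 1). Using
the window peak rather than per-bin comparisons makes one test per session
and needs no multiplicity correction. Random triggers are drawn with no
exclusion zone around true events; with sparse events this biases the test,
if anything, conservative.

**Onset estimation.** The triggered average is smoothed with a centered
moving average (0.15 s; it passes locally linear segments unchanged while
protecting the percent-of-peak anchors from noise), baseline-subtracted
(mean of the earliest 20 % of the window), and the rise is walked back from
the peak to the last sample below 10 % of peak; a least-squares line through
the contiguous rising samples with amplitude in [10 %, 90 %] of peak is
extrapolated to its zero crossing. "Zero" is the pre-event baseline, not
literal zero ΔF/F — the choice was open and the baseline-anchored version is
shift-invariant. On synthetic transients (rise τ 0.5 s, decay τ 2 s) the
estimator carries a small systematic early bias ≈ +0.09 s from the convex
exponential rise, well inside the ±0.3 s recovery tolerance at transient
SNR ≥ 5.

## Extracellular ephys

Multichannel voltage is referenced by subtracting the per-sample
across-channel median, which removes any signal shared by more than half
the channels exactly and leaves single-channel spikes untouched. Spikes are
detected per selected channel as samples whose absolute deviation from the
channel median exceeds k × SD (k = 10 by default) with SD = MAD/0.6745;
the median/MAD pair is used rather than mean/SD so that the spikes being
detected do not inflate the noise estimate. Crossings within 1 ms collapse
to the largest-amplitude sample. Absolute-value crossings cover both
polarities of the extracellular waveform.

**PETH and responsiveness.** rate(bin) = total spikes across trials /
(n_trials · bin width), default window ±5 s in 0.25 s bins (event-locked
effects here live at the 1–2 s scale; no canonical bin size exists, so a
bin that resolves it with margin was fixed once). The permutation null
rebuilds the PETH on `n_perm` uniformly random trigger sets of the same
size. A unit is responsive when ≥ 2 *consecutive* bins inside the response
window (default ±2.5 s) deviate ≥ 2 null-SD on the same side of the null.
A bare per-bin 2-SD rule is multiplicity-uncorrected; the two-consecutive-bin
run is the minimal correction and, with the ±2.5 s window (20 bins), holds
the empirical false-flag rate of untuned Poisson units under 0.1. The run
length is configurable down to 1 to recover the literal single-bin rule.

## SE-outcome conditioning (ΔPETH)

An SE is **Song-Inducing** if at least one song onset falls in
[SE onset, SE offset + 5 s], else **Quiet**; a song starting during an SE
counts for that SE, and ties go to the nearest preceding qualifying SE. A
song is **isolated** if it starts outside every SE and ≥ 5 s after every
earlier SE offset. Units enter the analysis if they fire ≥ 1 Hz during SE
epochs, capped at their first 40 SEs in session order (the cap is stated
for this analysis; no selection rule beyond "first" being given, session
order is the reproducible choice).

ΔPETH is scalarized as the mean rate over a [0, 2] s post-SE response
window (the SE response peaks near +1 s), Song-Inducing minus Quiet. This
window is the single most consequential free parameter of the analysis and
is exposed in `ConditioningConfig`. The null permutes the outcome labels
over the same SEs (class counts preserved, 1000 shuffles by default); the
unit is categorized Song-Inducing / Quiet when the observed ΔPETH falls
outside the upper/lower α/2 null quantile (two-sided α = 0.05), else
Agnostic. If one outcome class is empty the unit is Agnostic-by-default
with a degeneracy flag. At the population level each unit's ΔPETH is
standardized by its own null SD, and the empirical CDF of standardized
deltas is compared with the pooled standardized null; the one-sided p for
the mean shift reuses the per-unit shuffle draws as a joint null.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analyses assume:
SEs ≤ 10 s placed with ≥ 15 s onset spacing (so the 5 s isolation and 10 s
song-gap rules are satisfiable by construction); each SE elicits a song
with probability 0.65 (the observed fraction of exposures that lead to
song) after a lognormal latency with mode ≈ 1.5 s clipped to [0.3, 3] s;
songs of 4–12 syllables, each syllable a single-component sinusoid-FM tone
(carrier N(75, 8²) kHz clipped to 40–110, duration 20–60 ms, bandwidth
20 kHz, gaps 30–80 ms, ≤ 1 ms cosine ramps) on white noise at 20 dB
per-sample SNR. Photometry transients are double-exponential (rise 0.5 s,
decay 2 s) starting `lead_s` before each song onset. Units are
inhomogeneous-Poisson with Gaussian event kernels (SE kernel peaking +1 s
after exposure onset, song kernel peaking 0.5 s before the first syllable)
and a multiplicative gain on Song-Inducing SE responses; spike counts are
drawn on a 1 ms grid. Optional raw voltage places a fixed biphasic
template (negative peak 12 noise-SD) per spike on independent Gaussian
noise plus an arbitrary shared common-mode signal.

Deliberately absent: harmonic stacks, amplitude modulation, reverberation
and microphone directionality in the audio; hemodynamic/movement artifacts,
bleaching and isosbestic channels in photometry; bursting, refractory
dynamics beyond the detection collapse, electrode drift and waveform
overlap in ephys; and any coupling between social motivation and firing
beyond the planted kernels. Passing the validation studies therefore shows
that the estimators are correct and calibrated *under the stated model* —
real recordings can and do violate it, and thresholds (detect_z, k, rate
floor) would need checking against real noise floors.

## Validation studies and problem sizes

`songpeth.studies` packages the self-checks; the test suite and
`scripts/acceptance.py` run them at these sizes (chosen to make the
binomial error on every reported rate small relative to its acceptance
band):

* photometry type-I error: 500 signal-free sessions (240 s at 50 Hz, 20
  triggers, n_perm = 200) — expected rejection at α = 0.05 is
  10/201 ≈ 0.0497;
* onset recovery: 50 sessions at transient SNR 5, programmed lead 2.3 s;
* spike detection: 100 planted 12-SD templates in 60 s of noise at k = 10,
  plus 60 s of template-free noise;
* ΔPETH calibration/power: 200 units each at gain 1 and gain 2 (baseline
  4 Hz, SE response amplitude 4 Hz, 40 SEs, n_shuffle = 500), spread over
  10 independent SE schedules;
* segmentation recovery: one 60 s, 3-SE session at 20 dB SNR with every SE
  singing.

## Known limitations

* The song-onset "zero crossing" definition and the ΔPETH response window
  are conventions fixed here; alternatives (literal-zero crossing, per-bin
  ΔPETH curves) change numbers on real data.
* The feature bandwidth is sidelobe-limited at very high SNR (above).
* `label_se_outcomes` assigns each song to at most one SE; interleaved
  exposures faster than the follow window would need an explicit
  tie-breaking policy beyond "nearest preceding".
* The responsiveness test assumes stationary baseline rate over the
  session; slow drift inflates the null SD and costs power rather than
  validity.
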