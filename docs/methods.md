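# Methods

This note records the statistical model behind `spiba`, the concrete
numerical choices made where the method leaves freedom, what the synthetic
generators do and do not emulate, and the known limitations.

## The micro-movement-spike (MMS) standardization

A biorhythmic series is reduced to spikes in two stages.

1. **Empirical mean.** Local peaks of the raw series are detected and a
   two-parameter Gamma distribution is fitted to the peak amplitudes by
   maximum likelihood; its mean (which equals the sample mean of the peaks,
   an exact property of the Gamma MLE) is taken as the empirical reference
   level.  Using the peaks rather than all samples follows the procedure's
   phrasing ("upon peak detection, the overall empirical distribution mean
   is determined"); the choice only shifts the reference level, and the
   second-stage normalization is invariant to such shifts of scale.
2. **Normalization.** The absolute deviations from that mean form a
   rectified series; each of its peaks is mapped to
   `Peak / (Peak + Avrg)`, where `Avrg` is the arithmetic mean of all
   samples from the left flanking local minimum to the right flanking local
   minimum, **both endpoints included**.  The timestamps of the peaks are
   preserved.

Peak conventions: a peak is a strict local maximum; plateaus are represented
by their first sample; the flanking minima are the *nearest* local minima on
each side; series endpoints count as minima (never maxima) when they lie
below their neighboring run; maxima that still lack a flanking minimum are
discarded rather than truncated, so the ratio is always well defined.
`min_separation` (default 0) resolves close peaks keeping the larger;
`min_prominence` (default 0) ignores low-relief maxima — modality pipelines
may override both.

**Range note.** Because every sample in the min-to-min window is bounded by
the peak, `Avrg <= Peak`, and therefore MMS amplitudes actually live in
[1/2, 1); the documented (0, 1] contract is a superset.  Consequently any
Gamma distribution ascribed to MMS amplitudes is implicitly concentrated in
that band, which is why realistic MMS Gamma fits carry large shapes (tight
distributions around means of 0.55–0.9) and small scales (the NSR).

## Gamma inference

The MLE solves `log(a) - digamma(a) = log(mean) - mean(log x)` by bracketed
root finding (Minka's closed form as the starting point); the scale is
`mean/a` exactly.  95% confidence intervals are Wald intervals **on the log
scale** from the inverse Fisher information
`n * [[psi'(a), 1/b], [1/b, a/b^2]]`; log-scale intervals respect positivity
and have materially better small-sample coverage than natural-scale Wald
intervals.  Moments are closed forms: mean `a*b`, variance `a*b^2`, skewness
`2/sqrt(a)`, and kurtosis is reported as *full* kurtosis `3 + 6/a` (the
convention is recorded in every JSON output).  NSR = variance/mean = `b`.
Inputs must be >= 20 strictly positive samples with nonzero variance; a
zero-variance sample raises a degenerate-fit error rather than returning an
infinite shape.

The shape–scale power law is an ordinary least-squares fit of `log a` on
`log b`; in regulated signals the slope is negative (lower NSR, higher
shape, toward the Gaussian regime; shape 1 is the memoryless exponential
regime).

## Cardiac pipeline

* Filtering: 8th-order Butterworth band-pass 5–30 Hz followed by a 2nd-order
  band-stop from 40 Hz to `min(125, 0.99*Nyquist)` Hz (at the nominal 250 Hz
  sampling rate the printed 125 Hz edge coincides with Nyquist and is
  clipped).  Both filters are applied forward–backward (zero phase) so
  R-peak timing is not skewed; the band-stop is largely redundant after the
  band-pass and is kept for fidelity to the stated chain.
* R-peaks: local maxima separated by a 0.25 s refractory period whose
  prominence *and* height exceed `max(4 * median(|filtered|),
  0.3 * max(filtered))`.  The first term scales with the noise floor, the
  second anchors the threshold to the R-wave amplitude; the height condition
  rejects small bumps riding on the deep side lobes that sharp band-pass
  filtering leaves around each QRS.  On clean synthetic ECG recovery is
  exact; at 10 dB additive white noise (SNR defined on trace RMS power) the
  F1 score stays above 0.95.  The detector assumes a reasonably stationary
  QRS amplitude; a single large artifact would raise the amplitude-anchored
  term and can suppress genuine beats.
* Artifact policy: RR intervals outside [0.3, 2.0] s are flagged and
  excluded from Poincaré, spectral and Gamma computations.
* Poincaré: `SD1^2 = Var(diff)/2`, `SD2^2 = 2 Var(RR) - Var(diff)/2`
  (sample variances, ddof = 1), clipped at zero.
* Spectra: Lomb–Scargle periodogram of the unevenly sampled (beat time, RR)
  pairs on a linspace grid from 0.04 to 0.40 Hz in 0.005 Hz steps; LF and HF
  are trapezoid integrals sharing the 0.15 Hz grid point exactly, so
  LF + HF equals the full-band integral identically.  Records shorter than
  50 s set a low-frequency-resolution warning flag.
* Scalogram: the uneven IBI is linearly interpolated to a uniform 4 Hz grid,
  mean-removed, and transformed with a generalized Morse wavelet
  (gamma = 3, beta = 20, i.e. time-bandwidth 60) implemented directly in the
  frequency domain; scales are mapped to equivalent Fourier frequencies via
  the wavelet's peak frequency, and the display band is 0.04–0.4 Hz.  No
  pre-installed Python package provides Morse CWTs, so this small transform
  is implemented here and validated on tones (ridge within 0.03 Hz).
* Windowed RR statistics: 30 s windows advancing by 20 s (10 s overlap),
  `[start, start+30)`, trailing partial window dropped, intervals assigned
  by their terminal beat time; the mode uses a 10 ms histogram (the mode of
  a continuous variable is otherwise ill-defined); windows with fewer than
  3 intervals are flagged.  Windows slice the globally detected IBI series
  rather than re-detecting beats per window.
* The IBI Gamma/MMS signature treats the valid RR values as an amplitude
  sequence over beat order; spike event times are mapped back to beat times.

## Kinematics

The triaxial norm is gravity-inclusive (resting norms sit at 1 g), and
`to_si` multiplies by exactly 9.8.  "Center of position" is implemented as
the per-axis arithmetic mean of the raw acceleration over the task window,
reported next to the norm mean — an explicit reading of an under-specified
plotting quantity, configurable by simply computing something else from the
stored series.  EMG channels are parsed and stored but not analyzed.

## Face

* Shape normalization: per frame, subtract the landmark centroid, then
  divide by the standard deviation (ddof = 0) of the 68 landmark distances
  from the origin.  The map is idempotent and similarity-invariant.
* Parcellation: the default trigeminal map on iBUG numbering is
  V1 = {17–26, 36–47}, V2 = {27–35, 0–4, 12–16}, V3 = {5–11, 48–67} — a
  documented default, fully configurable via JSON.
* Speeds: cubic smoothing splines per coordinate (roughness penalty chosen
  by generalized cross-validation by default; 0 interpolates), differentiated
  analytically; speeds are computed on *normalized* coordinates so regional
  signatures are unitless and comparable across people.
* Regional signatures: each landmark's speed series runs the MMS pipeline
  independently (its own empirical mean); the per-landmark minimum spike
  count is relaxed to 5 because a 150-frame window yields few spikes per
  landmark, and the normalized amplitudes are pooled order-free across the
  region (>= 20 pooled spikes) for a single Gamma fit.  Landmarks whose
  speed range is below 1e-9 are treated as frozen and skipped.
* Moment triangles: vertices at (Gamma mean, variance, skewness) per region,
  marker size proportional to kurtosis in plots; the area is
  `||cross(B-A, C-A)||/2`.
* EMD trajectories: 150-frame (5 s) windows with 50% overlap by default (an
  alternative 10% overlap is a parameter, since both conventions appear in
  practice); per window and region the pooled MMS amplitude sample is
  compared to each reference sample by the 1-D Wasserstein distance
  (equal to the integral of the absolute CDF difference); windows with fewer
  than 5 spikes are flagged unreliable.  EMD is computed on MMS amplitude
  distributions — the only choice with a well-defined sample space.
* Transfer entropy: plug-in estimator of `I(Y_{t+1}; X_t | Y_t)` in bits
  with 3 equal-frequency bins and lag 1 frame, clipped at zero; an optional
  Miller–Madow correction is available.  On independent data the estimator's
  upward bias is roughly `(q-1)^2 q / (2 n ln 2)` bits (about 0.0017 bits at
  n = 5000, q = 3); the independence test tolerance of 0.05 bits sits well
  above it.  Constant series discretize to a single bin and give 0 by
  convention.

## Voice

Gammatone centers follow the classical auditory-toolbox ERB spacing between
100 Hz and Nyquist, ascending; the centers therefore depend on the audio
sampling rate, and at 44.1 kHz band 8 of 10 sits near 6.06 kHz, inside the
4–7 kHz sibilant range of interest (the selected band is the analysis
filter; no additional pre-filter is applied).  The band envelope is the
half-wave-rectified output of a causal 4th-order gammatone IIR filter,
smoothed by a zero-phase 4th-order Butterworth low-pass at 20 Hz, clipped at
zero and decimated to ~100 Hz.

Segmentation uses the session median amplitude: retained maxima are local
maxima strictly above it, retained minima local minima strictly below it;
when several maxima fall between two minima the highest survives (earliest
on ties), and the minima rule mirrors it; leading/trailing partial phases
are discarded so the sequence starts and ends at a minimum.  A constant or
strictly monotone envelope yields empty segments (silence is not an error).
Attack slope = rise/time from minimum to next maximum; decay slope is its
negative counterpart; areas are left-Riemann sums over `[min, max)` and
`[max, next min)`, which makes attack + decay exactly additive over a cycle.
Absolute slopes get the standard Gamma fit (flagged low-confidence under 20
cycles).  The memory score is the arithmetic mean of the longest forward and
backward digit spans, supplied manually.

## Group statistics

Kruskal–Wallis uses the rank-based chi-square statistic with tie correction
(when every pooled value is identical the statistic is 0 and p = 1 by
convention).  Pairwise emotion comparisons are two-group Kruskal–Wallis
tests (equivalent to the rank-sum test up to the chi-square approximation).
Raw p-values are reported with threshold marks at 0.01 (star) and 0.05
(circle); no multiple-testing correction is applied by default because the
marks convey per-comparison evidence, but a Benjamini–Hochberg option is
provided.

## Synthetic data: what it emulates, and what it does not

The generators produce, with fixed seeds and byte-identical outputs:
IBI series (baseline RR 0.9 s with optional 0.1 Hz / 0.25 Hz oscillations,
Gaussian jitter, or Gamma-structured fluctuations), QRS-like ECG traces
(Mexican-hat templates, optional white noise at a stated RMS SNR), triaxial
accelerometer traces per task profile, 68-landmark facial trajectories with
region-controlled speed structure, and burst-structured speech envelopes
with prescribed slope distributions.

The centerpiece inverts the MMS normalization analytically.  The emitted
raw signal is `C - A*d(t)` where `d` is a train of unit cells (valleys at
level 1, apexes at 6, power-law flanks `(j/L)^gamma`); the pipeline's
first-stage peaks then sit at the cell valleys, so the estimated Gamma mean
is the known average valley level.  A short calibration block of lower,
randomized valleys supplies first-stage variance while keeping every main
valley above the estimated mean, so the deviation series reproduces the
designed cells without zero crossings, and each normalization window is
exactly one cell; the flank exponent of each cell is solved by monotone
root finding so that `Peak/(Peak+Avrg)` equals the target draw.
Calibration artifacts stay strictly below a prominence threshold reported
in the ground truth, which the pipeline uses to ignore them.  The
construction round-trips through the full pipeline to ~1e-12, and target
draws outside the realizable (≈0.54, 0.93) amplitude band are redrawn
(a negligible fraction under the defaults, e.g. Gamma(400, 0.0017)).

Default study conditions, chosen once as representative: IBI recovery runs
use 300 spikes with RR values confined to [0.92, 1.10] s (inside the
artifact band); IMU task profiles set fluctuation amplitude and Gamma
targets per task (resting 0.004 g / scale 0.0016 … walking 0.035 g /
scale 0.0027), ordered so that more vigorous tasks are noisier; facial
regions default to a common amplitude mean of ~0.68–0.72 with NSR ordered
V1 < V2 < V3; voice envelopes use 200–250 cycles with slopes from
Gamma(4, 0.5) re-quantized to the sample grid (< 1% distortion).

What passing tests show — and what they do not: the generators exercise the
*statistical* structure each stage assumes (spike amplitude distributions,
oscillation bands, burst geometry), so green tests demonstrate that the
implementation measures what it claims to measure.  They do not emulate
full ECG morphology (P/T waves), realistic facial appearance, speech
phonetics, sensor drift, or movement artifacts, so performance on real
recordings — in particular R-peak detection under electrode motion and
landmark jitter from tracking software — is not established by this suite.
For clips shorter than ~270 frames the face generator falls back to an
approximate spike train (light valley jitter, no calibration block) whose
amplitudes deviate from the targets by a few percent; exact-recovery tests
therefore feed speeds directly via `gen_region_speeds`, while
position-level tests assert ordering rather than coverage, since spline
re-differentiation rounds spike apexes systematically.

## Problem sizes and calibration facts

Parameter-recovery coverage is assessed over 100 seeded runs per modality
(300 spikes per IBI/IMU run, 4x75 pooled spikes per face run, 250 cycles
per voice run); observed joint coverage of the 95% CIs (both parameters) is
93–97%, against a >= 90% criterion.  Kruskal–Wallis type-I error is
calibrated over 1000 null simulations at n = 20 per group.  The EMD oracle
comparison uses 10,000 samples per distribution.  The exponential
shape-1 check uses 100,000 draws with a 2% tolerance (asymptotic SE of the
shape is ~0.004 there).

## Known limitations

* The MMS range restriction to [1/2, 1) means Gamma fits of MMS amplitudes
  describe a truncated family; fits are interpreted comparatively (NSR
  orderings, trajectories), not as literal densities on (0, inf).
* Wald CIs, even on the log scale, are asymptotic; below ~50 spikes their
  coverage degrades and fits are flagged rather than trusted.
* The R-peak detector is deliberately simple (no beat-morphology
  classification) and assumes stable QRS polarity and amplitude.
* The transfer-entropy estimator is a binned plug-in with no embedding
  beyond lag 1; it detects directed coupling but its absolute values are
  bin-dependent.
* Facial signatures depend on the chosen landmark-to-region map; the
  default is anatomically motivated but configurable, and results should be
  reported together with the map used.
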