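# spiba — spike-based biometrics

`spiba` is a statistical toolkit for **personalized biometrics from
biorhythmic time series**: wearable ECG, triaxial accelerometry, 68-landmark
facial video kinematics and speech audio.  It is aimed at researchers in
digital phenotyping and movement neuroscience who need a *unified*,
distribution-free standardization of heterogeneous sensor streams so that
signals from different people, body parts and modalities become directly
comparable.

## The method

Every modality is reduced to **micro-movement spikes (MMS)**.  Given a raw
series, its local peaks are detected and the empirical Gamma mean of the
peak amplitudes is estimated by maximum likelihood.  The absolute deviations
from that mean form a rectified series whose peaks are normalized by their
local min-to-min window:

    MMS = Peak / (Peak + Avrg_min_to_min)

where `Avrg_min_to_min` is the mean of all samples between the two local
minima flanking the peak (inclusive).  The ratio is unitless, bounded in
(0, 1], invariant to uniform signal rescaling — removing allometric
(body-size) effects — and preserves the original spike timestamps.

The MMS amplitudes are then fitted with a two-parameter Gamma distribution
(shape *a*, scale *b*) by MLE with 95% confidence intervals.  Since
Γμ = a·b and Γσ² = a·b², the **noise-to-signal ratio** NSR = Γσ²/Γμ = *b*
is simply the Gamma scale; shape 1 is the memoryless exponential regime
(random, noisy signals), while large shapes approach the Gaussian regime
(predictive, well-regulated signals).  Across signatures, log *a* and
log *b* follow a scaling power law with negative slope.

On top of this engine the package provides:

* **cardiac** — Butterworth ECG preprocessing (5–30 Hz band-pass, 40 Hz–
  near-Nyquist band-stop), R-peak detection, inter-beat intervals, Poincaré
  SD1/SD2, Lomb–Scargle LF (0.04–0.15 Hz) / HF (0.15–0.4 Hz) band powers,
  generalized-Morse-wavelet scalograms, 30-s windowed RR statistics and the
  IBI Gamma/MMS signature;
* **kinematics** — Euclidean norm of triaxial acceleration (1 g = 9.8 m/s²),
  per-(location, task) signatures, and the task parameter space;
* **face** — shape normalization (centroid to (0,0), SD of landmark
  distances to 1), trigeminal V1/V2/V3 parcellation, spline-smoothed speed
  fields, pooled regional Gamma signatures, Gamma-moment triangles, windowed
  Earth-mover's-distance trajectories against reference expression
  signatures, and pairwise transfer entropy between regions;
* **voice** — gammatone (ERB) filter-bank envelopes, median-thresholded
  attack/decay segmentation, slope and area stochastics, and the memory
  score;
* **compare** — Kruskal–Wallis tests and pairwise EMD / p-value matrices
  with significance marks;
* **synthetic** — seeded generators for every input, including an exact
  inverse of the MMS normalization so pipeline outputs can be checked
  against prescribed Gamma draws.

## Worked example

Simulate a leg-worn accelerometer during walking and recover its stochastic
signature:

```python
from spiba.synthetic import gen_imu
from spiba.kinematics import imu_signature

tri, truth = gen_imu(task="walking", location="leg", seed=7)
sig = imu_signature(tri, min_prominence=truth["min_prominence"])
print(sig.gamma.to_dict())
```

prints (abbreviated):

```json
{
  "shape": 285.302129,
  "scale": 0.002333,
  "shape_ci": [243.133758, 334.784053],
  "scale_ci": [0.001988, 0.002738],
  "mean": 0.66549,
  "skewness": 0.118407,
  "nsr": 0.002333,
  "n_samples": 300
}
```

The generator injected MMS amplitudes drawn from Gamma(shape = 250,
scale = 0.0027); the fitted NSR of 0.00233 (95% CI 0.00199–0.00274) covers
the injected scale, and the narrow CI reflects the 300 spikes available.  A
resting recording produces a visibly smaller NSR — the basis for separating
tasks in the (NSR, center-of-position) plane.

The same analyses are available from the shell:

```bash
spiba simulate --modality imu --seed 7 --out sim/
spiba imu --input sim/acc.csv --meta sim/meta.json --json signature.json
spiba ecg --input ecg.csv --fs 250 --json out.json --scalogram out.png
```

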