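"""Modality-agnostic micro-movement spike (MMS) engine.

This module implements the standardization at the heart of the package:
biorhythmic time series are reduced to trains of unitless spike amplitudes

    MMS = Peak / (Peak + Avrg_min_to_min)

where ``Peak`` is a local maximum of the absolute-deviation series (deviations
of the raw signal from its empirically estimated Gamma mean) and
``Avrg_min_to_min`` is the arithmetic mean of all samples between the local
minima flanking that peak (both minima included).  The MMS amplitudes are then
characterized by a two-parameter Gamma distribution fitted by maximum
likelihood; the Gamma scale equals the noise-to-signal ratio (variance/mean)
and is the primary stochastic signature used throughout the package.

Because the flanking-window average can never exceed the peak itself, MMS
amplitudes are structurally confined to [1/2, 1); the documented contract
(0, 1] is a superset of this band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, special, optimize, stats

from .errors import (
    DegenerateFitError,
    DegenerateWindowError,
    InsufficientDataError,
    InvalidInputError,
)

__all__ = [
    "UniformSeries",
    "PeakSet",
    "MMSSeries",
    "GammaSignature",
    "PowerLawFit",
    "detect_peaks",
    "empirical_gamma_fit",
    "deviation_series",
    "mms_normalize",
    "mms_pipeline",
    "fit_power_law",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class UniformSeries:
    """A uniformly sampled scalar signal.

    Parameters
    ----------
    timestamps : ndarray
        Strictly increasing sample times in seconds with uniform spacing
        ``1/sampling_rate`` (relative tolerance 1e-9).
    values : ndarray
        Signal amplitude at each timestamp.  Units are carried as metadata
        (``"mV"``, ``"g"``, ``"m/s^2"``, ``"px/s"``, ``""`` for unitless).
    sampling_rate : float
        Sampling rate in Hz, > 0.
    """

    timestamps: np.ndarray
    values: np.ndarray
    sampling_rate: float
    units: str = ""

    def __post_init__(self):
        ts = np.asarray(self.timestamps, dtype=float)
        vs = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "values", vs)
        if ts.ndim != 1 or vs.ndim != 1 or ts.size != vs.size:
            raise InvalidInputError("timestamps and values must be 1-D and equally long")
        if not self.sampling_rate > 0:
            raise InvalidInputError("sampling_rate must be positive")
        if ts.size >= 2:
            dt = np.diff(ts)
            expected = 1.0 / self.sampling_rate
            if np.any(dt <= 0):
                raise InvalidInputError("timestamps must be strictly increasing")
            if np.max(np.abs(dt - expected)) > 1e-9 * max(expected, 1.0):
                raise InvalidInputError("timestamps are not uniformly spaced at sampling_rate")

    @classmethod
    def from_rate(cls, values, sampling_rate: float, t0: float = 0.0, units: str = "") -> "UniformSeries":
        values = np.asarray(values, dtype=float)
        ts = t0 + np.arange(values.size) / float(sampling_rate)
        return cls(ts, values, float(sampling_rate), units)

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return (len(self) - 1) / self.sampling_rate if len(self) else 0.0


@dataclass(frozen=True)
class PeakSet:
    """Local maxima of a series together with their flanking local minima.

    ``left_min_indices[i] < peak_indices[i] < right_min_indices[i]`` for every
    peak; the flanking minima are the *nearest* local minima on each side, so
    the min-to-min window of a peak spans exactly one oscillation cell.
    Boundary maxima without a flanking minimum on one side are discarded.
    """

    peak_indices: np.ndarray
    left_min_indices: np.ndarray
    right_min_indices: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.peak_indices, dtype=np.intp)
        l = np.asarray(self.left_min_indices, dtype=np.intp)
        r = np.asarray(self.right_min_indices, dtype=np.intp)
        object.__setattr__(self, "peak_indices", p)
        object.__setattr__(self, "left_min_indices", l)
        object.__setattr__(self, "right_min_indices", r)
        if not (p.size == l.size == r.size):
            raise InvalidInputError("peak/min index arrays must have equal length")
        if p.size:
            if not (np.all(l < p) and np.all(p < r)):
                raise InvalidInputError("flanking minima must bracket each peak")
            if np.any(np.diff(p) <= 0):
                raise InvalidInputError("peak indices must be strictly increasing")

    def __len__(self) -> int:
        return self.peak_indices.size


@dataclass(frozen=True)
class MMSSeries:
    """Micro-movement spikes: peak event times plus unitless amplitudes in (0, 1]."""

    event_times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.event_times, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "event_times", t)
        object.__setattr__(self, "amplitudes", a)
        if t.size != a.size:
            raise InvalidInputError("event_times and amplitudes must be equally long")
        if a.size and (np.any(a <= 0.0) or np.any(a > 1.0)):
            raise InvalidInputError("MMS amplitudes must lie in (0, 1]")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise InvalidInputError("event times must be strictly increasing")

    def __len__(self) -> int:
        return self.amplitudes.size


@dataclass(frozen=True)
class GammaSignature:
    """MLE Gamma(shape, scale) fit with 95% CIs and closed-form moments.

    The noise-to-signal ratio (NSR) is variance/mean = scale.  Kurtosis is
    reported as *full* kurtosis ``3 + 6/shape`` (the Gaussian reference is 3),
    recorded in :meth:`to_dict` under ``kurtosis_convention``.
    Confidence intervals are asymptotic Wald intervals computed on the log
    scale from the observed information, which respects positivity and has
    better small-sample coverage than intervals on the natural scale.
    """

    shape: float
    scale: float
    shape_ci: tuple
    scale_ci: tuple
    n_samples: int

    def __post_init__(self):
        if not (self.shape > 0 and self.scale > 0):
            raise InvalidInputError("shape and scale must be positive")

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def variance(self) -> float:
        return self.shape * self.scale ** 2

    @property
    def skewness(self) -> float:
        return 2.0 / np.sqrt(self.shape)

    @property
    def kurtosis(self) -> float:
        return 3.0 + 6.0 / self.shape

    @property
    def nsr(self) -> float:
        return self.scale

    @property
    def moment_point(self) -> np.ndarray:
        """(mean, variance, skewness) coordinates used in moment-space plots."""
        return np.array([self.mean, self.variance, self.skewness])

    def to_dict(self) -> dict:
        return {
            "shape": self.shape,
            "scale": self.scale,
            "shape_ci": list(self.shape_ci),
            "scale_ci": list(self.scale_ci),
            "mean": self.mean,
            "variance": self.variance,
            "skewness": self.skewness,
            "kurtosis": self.kurtosis,
            "kurtosis_convention": "full (Gaussian = 3)",
            "nsr": self.nsr,
            "n_samples": self.n_samples,
        }


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log(shape) on log(scale): ``log a = slope*log b + intercept``."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int = 0


# --------------------------------------------------------------------------
# extrema machinery
# --------------------------------------------------------------------------

def _local_extrema(values: np.ndarray):
    """Indices of local maxima and minima with plateaus collapsed.

    A run of equal samples counts as a single extremum represented by its
    first index.  Endpoints are never extrema.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 3:
        return np.empty(0, np.intp), np.empty(0, np.intp)
    keep = np.empty(n, dtype=bool)
    keep[0] = True
    np.not_equal(v[1:], v[:-1], out=keep[1:])
    run_starts = np.nonzero(keep)[0]
    rv = v[run_starts]
    if rv.size < 3:
        return np.empty(0, np.intp), np.empty(0, np.intp)
    d = np.sign(np.diff(rv))
    maxima = run_starts[1:-1][(d[:-1] > 0) & (d[1:] < 0)]
    minima = run_starts[1:-1][(d[:-1] < 0) & (d[1:] > 0)]
    return maxima.astype(np.intp), minima.astype(np.intp)


def _enforce_separation(values: np.ndarray, peaks: np.ndarray, min_gap: int) -> np.ndarray:
    """Greedy resolution: among peaks closer than ``min_gap`` keep the larger
    (earlier index on ties)."""
    if min_gap <= 1 or peaks.size <= 1:
        return peaks
    order = np.lexsort((peaks, -values[peaks]))  # height desc, index asc on ties
    keep = np.zeros(peaks.size, dtype=bool)
    kept_positions: list[int] = []
    for j in order:
        p = peaks[j]
        if all(abs(p - q) >= min_gap for q in kept_positions):
            keep[j] = True
            kept_positions.append(p)
    return peaks[keep]


def detect_peaks(
    series: UniformSeries,
    min_separation: float = 0.0,
    min_prominence: float = 0.0,
) -> PeakSet:
    """Detect strict local maxima together with their flanking local minima.

    Parameters
    ----------
    series : UniformSeries
        Signal to scan (at least 3 samples).
    min_separation : float
        Minimum peak-to-peak distance in seconds; among closer peaks the
        larger survives.
    min_prominence : float
        Minimum topographic prominence in signal units; 0 disables the filter.

    Notes
    -----
    Plateau maxima are represented by the first sample of the plateau.
    Maxima lacking a local minimum on either side (boundary peaks) are
    discarded so the min-to-min normalization window is always well defined.
    """
    if len(series) < 3:
        raise InvalidInputError("peak detection requires at least 3 samples")
    if min_separation < 0:
        raise InvalidInputError("min_separation must be >= 0")
    v = series.values
    maxima, minima = _local_extrema(v)
    if maxima.size and min_prominence > 0:
        prom = signal.peak_prominences(v, maxima)[0]
        maxima = maxima[prom >= min_prominence]
    if maxima.size:
        gap = int(round(min_separation * series.sampling_rate))
        maxima = _enforce_separation(v, maxima, gap)
        maxima = np.sort(maxima)
    # boundary runs count as minima (never maxima) when below their neighbor
    ends = []
    i = 1
    while i < v.size and v[i] == v[0]:
        i += 1
    if i < v.size and v[0] < v[i]:
        ends.append(0)
    j = v.size - 2
    while j >= 0 and v[j] == v[-1]:
        j -= 1
    if j >= 0 and v[-1] < v[j]:
        ends.append(j + 1)  # first index of the trailing run
    if ends:
        minima = np.unique(np.concatenate([minima, np.asarray(ends, np.intp)]))
    # nearest flanking local minima; discard boundary peaks without one
    if maxima.size == 0 or minima.size == 0:
        e = np.empty(0, np.intp)
        return PeakSet(e, e, e)
    pos = np.searchsorted(minima, maxima)
    has_left = pos > 0
    has_right = pos < minima.size
    ok = has_left & has_right
    maxima = maxima[ok]
    pos = pos[ok]
    return PeakSet(maxima, minima[pos - 1], minima[pos])


# --------------------------------------------------------------------------
# Gamma MLE
# --------------------------------------------------------------------------

def _gamma_mle_shape(s: float) -> float:
    """Solve ``log(a) - digamma(a) = s`` for the Gamma MLE shape.

    The left side is strictly decreasing from +inf (a -> 0) to 0 (a -> inf),
    so a unique positive root exists for every s > 0.
    """
    # classical closed-form starting point (Minka 2002)
    a0 = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    f = lambda a: np.log(a) - special.digamma(a) - s
    lo, hi = a0, a0
    while f(lo) < 0:
        lo /= 8.0
    while f(hi) > 0:
        hi *= 8.0
    return float(optimize.brentq(f, lo, hi, xtol=1e-14, rtol=1e-14))


def empirical_gamma_fit(samples, min_samples: int = 20) -> GammaSignature:
    """Fit a two-parameter Gamma distribution by maximum likelihood.

    Parameters
    ----------
    samples : array-like
        Strictly positive observations, at least ``min_samples`` of them,
        with nonzero variance.

    Returns
    -------
    GammaSignature
        MLE shape/scale, 95% confidence intervals and closed-form moments.
        The MLE constraint ``scale = sample_mean / shape`` holds exactly, so
        the fitted Gamma mean equals the sample mean.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < min_samples:
        raise InsufficientDataError(
            f"gamma fit requires >= {min_samples} samples, got {x.size}"
        )
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise InvalidInputError("gamma fit requires strictly positive finite samples")
    mean = float(np.mean(x))
    s = np.log(mean) - float(np.mean(np.log(x)))
    if s <= 0 or np.var(x) == 0.0:
        raise DegenerateFitError("zero-variance sample: gamma fit undefined")
    a = _gamma_mle_shape(s)
    b = mean / a
    n = x.size
    # observed (= expected, for the Gamma family) information per observation
    tri = special.polygamma(1, a)
    det = tri * a / b ** 2 - 1.0 / b ** 2
    var_a = (a / b ** 2) / (n * det)
    var_b = tri / (n * det)
    z = stats.norm.ppf(0.975)
    se_log_a = np.sqrt(var_a) / a
    se_log_b = np.sqrt(var_b) / b
    shape_ci = (a * np.exp(-z * se_log_a), a * np.exp(z * se_log_a))
    scale_ci = (b * np.exp(-z * se_log_b), b * np.exp(z * se_log_b))
    return GammaSignature(a, b, shape_ci, scale_ci, n)


# --------------------------------------------------------------------------
# deviation + normalization
# --------------------------------------------------------------------------

def deviation_series(series: UniformSeries, gamma_mean: float) -> UniformSeries:
    """Absolute deviations ``|x(t) - gamma_mean|`` with timestamps preserved."""
    if not gamma_mean > 0:
        raise InvalidInputError("gamma_mean must be positive")
    return UniformSeries(
        series.timestamps,
        np.abs(series.values - gamma_mean),
        series.sampling_rate,
        series.units,
    )


def mms_normalize(series: UniformSeries, peaks: PeakSet) -> MMSSeries:
    """Apply the min-to-min spike normalization ``Peak/(Peak + Avrg)``.

    ``Avrg`` is the arithmetic mean of all samples from the left flanking
    minimum to the right flanking minimum, both endpoints included.  The
    result is unitless and invariant to uniform rescaling of the signal.
    """
    v = series.values
    n = v.size
    if peaks.peak_indices.size and (
        peaks.peak_indices[-1] >= n or peaks.right_min_indices[-1] >= n
    ):
        raise InvalidInputError("peak indices out of range for series")
    amps = np.empty(len(peaks))
    for i, (l, p, r) in enumerate(
        zip(peaks.left_min_indices, peaks.peak_indices, peaks.right_min_indices)
    ):
        peak = v[p]
        if peak <= 0:
            raise InvalidInputError("every peak amplitude must be positive")
        avrg = float(np.mean(v[l : r + 1]))
        denom = peak + avrg
        if denom <= 0:
            raise DegenerateWindowError("Peak + Avrg window sum is not positive")
        amps[i] = peak / denom
    return MMSSeries(series.timestamps[peaks.peak_indices], amps)


def mms_pipeline(
    series: UniformSeries,
    min_separation: float = 0.0,
    min_prominence: float = 0.0,
    min_spikes: int = 20,
):
    """Full MMS standardization of a raw series.

    Stage 1: detect peaks of the raw series, fit Gamma to the peak amplitudes
    and take the fitted Gamma mean (equal to the sample mean of the peaks).
    Stage 2: build the absolute-deviation series, detect its peaks, normalize
    them min-to-min and fit Gamma to the resulting MMS amplitudes.

    Returns
    -------
    (MMSSeries, GammaSignature)

    Raises
    ------
    Errors from any stage are re-raised with the stage name prefixed.
    """

    def _stage(label, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except (InvalidInputError, InsufficientDataError, DegenerateFitError,
                DegenerateWindowError) as exc:
            exc.args = (f"[{label}] {exc.args[0] if exc.args else ''}",) + exc.args[1:]
            raise

    pk1 = _stage("stage 1: raw peaks", detect_peaks, series, min_separation, min_prominence)
    amps1 = series.values[pk1.peak_indices]
    if amps1.size < min_spikes:
        raise DegenerateFitError(
            f"[stage 1: raw peaks] only {amps1.size} peaks found, need >= {min_spikes}"
        )
    sig1 = _stage("stage 1: gamma mean", empirical_gamma_fit, amps1, min_samples=min_spikes)
    dev = _stage("stage 2: deviations", deviation_series, series, sig1.mean)
    pk2 = _stage("stage 2: deviation peaks", detect_peaks, dev, min_separation, min_prominence)
    if len(pk2) < min_spikes:
        raise InsufficientDataError(
            f"[stage 2: deviation peaks] only {len(pk2)} spikes, need >= {min_spikes}"
        )
    mms = _stage("stage 2: normalization", mms_normalize, dev, pk2)
    sig = _stage("stage 2: gamma fit", empirical_gamma_fit, mms.amplitudes, min_samples=min_spikes)
    return mms, sig


def fit_power_law(signatures) -> PowerLawFit:
    """OLS regression of log(shape) on log(scale) across signatures.

    In maturing, well-regulated biosignals the relation has negative slope:
    as the noise-to-signal ratio (scale) decreases the shape increases
    towards the Gaussian range of the Gamma family.
    """
    sigs = list(signatures)
    if len(sigs) < 2:
        raise InvalidInputError("power-law fit requires at least 2 signatures")
    log_b = np.log([s.scale for s in sigs])
    log_a = np.log([s.shape for s in sigs])
    if np.unique(log_b).size < 2:
        raise InvalidInputError("power-law fit requires at least 2 distinct scales")
    res = stats.linregress(log_b, log_a)
    return PowerLawFit(float(res.slope), float(res.intercept), float(res.rvalue ** 2), len(sigs))
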