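"""Seeded generators for every input the analysis pipelines consume.

No participant data ships with the package; instead each modality has a
generator that emits signals with the exact statistical structure the
analyses assume, together with machine-readable ground truth, so every stage
is testable end to end.

The centerpiece is :func:`mms_spike_train`, which *inverts* the
micro-movement-spike normalization: given target spike amplitudes
m ~ Gamma(shape, scale) it synthesizes a raw waveform such that running the
full two-stage MMS pipeline (raw peaks -> empirical Gamma mean -> absolute
deviations -> min-to-min normalization) returns exactly those amplitudes.
The construction works as follows.  The raw signal is an inverted spike
train ``r = C - A*d`` built from unit cells of the template ``d``: valleys at
level 1 separated by apexes at level 6 with power-law flanks
``(j/L)**gamma``.  The local *maxima* of ``r`` then sit at the cell valleys,
so the first-stage empirical Gamma mean is the average valley level, which
the generator knows exactly.  A short leading calibration block of valleys
at randomized lower levels supplies the first-stage fit with variance while
keeping every main valley *above* the estimated mean, so the deviation
series reproduces the designed cells without zero crossings and each
normalization window is exactly one cell.  The flank exponent of each cell
is solved (1-D monotone root find) so that Peak/(Peak+window mean) equals
the target amplitude.  Calibration artifacts are strictly smaller than a
known prominence threshold, reported in the ground truth, which the pipeline
uses to ignore them.

Because the min-to-min window average can never exceed the peak, realizable
MMS amplitudes live in roughly (0.54, 0.93); target draws outside the band
are redrawn (a negligible fraction under the default parameters, which were
chosen to concentrate the Gamma mass well inside it).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .cardiac import IBISeries
from .core import UniformSeries
from .errors import ConfigurationError, InvalidInputError
from .face import FaceGrid, N_LANDMARKS, RegionMap
from .kinematics import TriaxialSeries
from .voice import EnvelopeSeries, erb_center_frequencies

__all__ = [
    "mms_spike_train",
    "gen_ibi",
    "gen_ecg",
    "gen_imu",
    "gen_face",
    "gen_region_speeds",
    "gen_voice",
    "gen_envelope",
    "TASK_PROFILES",
    "FACE_REGION_TARGETS",
]

# template geometry (dimensionless deviation units)
_H_MAIN = 1.0      # main valley level
_P_MAIN = 6.0      # main apex level
_P_CAL = 3.5       # calibration apex level
_THETA = _P_CAL - 0.87   # prominence threshold separating spikes from artifacts
_CAL_LO, _CAL_HI = 0.2, 0.8   # calibration valley levels
_GAMMA_LO, _GAMMA_HI = 0.02, 80.0  # flank exponent range


def _rng_of(rng, seed):
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def _flank_sum(gamma: float, log_js: np.ndarray) -> float:
    return float(np.exp(gamma * log_js).sum())


def mms_spike_train(
    n_spikes: int,
    shape: float = 400.0,
    scale: float = 0.0017,
    *,
    baseline: float = None,
    amplitude: float = 1.0,
    flank: int = 8,
    n_calibration: int = None,
    calibration_flank: int = 4,
    rng=None,
    seed: int = None,
):
    """Raw signal whose pipeline MMS amplitudes are iid Gamma(shape, scale).

    Parameters
    ----------
    n_spikes : int
        Number of prescribed spikes (>= 30).
    shape, scale : float
        Target Gamma parameters of the MMS amplitudes.  The product
        (the Gamma mean) must sit well inside the realizable (0.54, 0.93)
        amplitude band; the defaults give mean 0.68, sd 0.034.
    baseline, amplitude : float
        The emitted signal is ``baseline - amplitude * d`` with the template
        ``d`` in [0.2, 6]; ``baseline`` defaults to ``7 * amplitude`` so all
        signal peaks are positive.
    flank : int
        Samples per spike flank; one cell spans ``2 * flank`` samples.

    Returns
    -------
    (values, truth) : ndarray and dict
        ``truth`` holds the prescribed amplitudes (``"mms"``, in spike
        order), the prominence threshold the pipeline should use
        (``"min_prominence"``), the exact first-stage Gamma mean, the apex
        sample indices, and the redraw count for out-of-band targets.
    """
    rng = _rng_of(rng, seed)
    if n_spikes < 30:
        raise InvalidInputError("need n_spikes >= 30")
    if not (shape > 0 and scale > 0 and amplitude >= 0):
        raise InvalidInputError("shape, scale must be positive; amplitude nonnegative")
    if flank < 2 or calibration_flank < 2:
        raise InvalidInputError("flank lengths must be >= 2")
    K = n_calibration if n_calibration is not None else max(4, min(40, n_spikes // 12))
    if not 4 <= K <= max(4, n_spikes // 10):
        raise ConfigurationError("n_calibration must be in [4, n_spikes/10]")

    h_cal = rng.uniform(_CAL_LO, _CAL_HI, K)
    # Valley levels whose peaks survive stage-1 detection: the first
    # calibration valley and the last main valley are boundary peaks with
    # sub-threshold prominence (the entry/exit stubs climb only 0.6), and the
    # first main valley's left barrier is the last calibration apex, giving
    # it prominence (P_cal - H) = 2.5 < theta, so all three are dropped.
    stage1_levels = np.concatenate([h_cal[1:], np.full(n_spikes - 1, _H_MAIN)])
    wbar = float(np.mean(stage1_levels))
    vt = _H_MAIN - wbar          # main valley height in the deviation series
    pi = _P_MAIN - wbar          # main apex height in the deviation series
    if not (vt > 0 and _P_CAL - wbar < _THETA):
        raise ConfigurationError("calibration block breaks the template margins")

    L = flank
    log_js = np.log(np.arange(1, L) / L)
    denom = 2 * L + 1

    def m_of_gamma(g: float) -> float:
        avg = (2 * L * vt + 2 * (_P_MAIN - _H_MAIN) * _flank_sum(g, log_js) + pi) / denom
        return pi / (pi + avg)

    m_lo = m_of_gamma(_GAMMA_LO) + 2e-3
    m_hi = m_of_gamma(_GAMMA_HI) - 2e-3
    m = rng.gamma(shape, scale, n_spikes)
    n_redrawn = 0
    while True:
        bad = (m <= m_lo) | (m >= m_hi)
        nb = int(bad.sum())
        if nb == 0:
            break
        n_redrawn += nb
        if n_redrawn > 20 * n_spikes:
            raise ConfigurationError(
                "target Gamma(shape, scale) has almost no mass in the "
                f"realizable MMS band ({m_lo:.3f}, {m_hi:.3f})"
            )
        m[bad] = rng.gamma(shape, scale, nb)

    # invert Peak/(Peak + Avrg) = m for the flank exponent, cell by cell
    s_target = ((denom * pi * (1.0 - m) / m) - pi - 2 * L * vt) / (2 * (_P_MAIN - _H_MAIN))
    gammas = np.array([
        brentq(lambda g, st=st: _flank_sum(g, log_js) - st, _GAMMA_LO, _GAMMA_HI,
               xtol=1e-13, rtol=8.9e-16)
        for st in s_target
    ])

    cf = calibration_flank
    cal_rise = np.arange(1, cf) / cf
    js = np.arange(1, L) / L
    parts = [np.array([h_cal[0] + 0.6, h_cal[0] + 0.3])]
    length = 2
    apex_indices = []
    valley_indices = []
    for k in range(K):
        v_here = h_cal[k]
        v_next = h_cal[k + 1] if k + 1 < K else _H_MAIN
        valley_indices.append(length)
        parts.append(np.concatenate([
            [v_here],
            v_here + (_P_CAL - v_here) * cal_rise,
            [_P_CAL],
            _P_CAL + (v_next - _P_CAL) * cal_rise,
        ]))
        length += 2 * cf
    for i in range(n_spikes):
        prof = (_P_MAIN - _H_MAIN) * js ** gammas[i]
        valley_indices.append(length)
        apex_indices.append(length + L)
        parts.append(np.concatenate([[_H_MAIN], _H_MAIN + prof,
                                     [_P_MAIN], _H_MAIN + prof[::-1]]))
        length += 2 * L
    valley_indices.append(length)
    parts.append([_H_MAIN, _H_MAIN + 0.3, _H_MAIN + 0.6])
    length += 3
    d = np.concatenate(parts)

    c = baseline if baseline is not None else amplitude * (_P_MAIN + 1.0)
    if amplitude > 0 and c - amplitude * _H_MAIN <= 0:
        raise InvalidInputError("baseline too low: raw peak amplitudes not positive")
    values = c - amplitude * d
    truth = {
        "mms": m,
        "shape": shape,
        "scale": scale,
        "min_prominence": amplitude * _THETA,
        "stage1_mean": c - amplitude * wbar,
        "apex_indices": np.asarray(apex_indices, dtype=np.intp),
        "valley_indices": np.asarray(valley_indices, dtype=np.intp),
        "n_redrawn": n_redrawn,
        "baseline": c,
        "amplitude": amplitude,
        "mms_band": (m_lo, m_hi),
    }
    return values, truth


def _approx_speed_train(n_samples, shape, scale, amplitude, rng, flank=4):
    """Length-exact spike train with *approximately* Gamma MMS amplitudes.

    Used for short recordings (e.g. 150-frame emotion clips) where the exact
    calibrated construction does not fit; valleys are lightly jittered for
    first-stage variance, which perturbs the realized amplitudes by a few
    percent.  Returns (values, valley_indices).
    """
    L = flank
    log_js = np.log(np.arange(1, L) / L)
    denom = 2 * L + 1
    pi = _P_MAIN - _H_MAIN

    def m_of_gamma(g):
        avg = (2 * pi * _flank_sum(g, log_js) + pi) / denom
        return pi / (pi + avg)

    m_lo = m_of_gamma(_GAMMA_LO) + 2e-3
    m_hi = m_of_gamma(_GAMMA_HI) - 2e-3
    n_cells = max(3, (n_samples - 6) // (2 * L))
    m = np.clip(rng.gamma(shape, scale, n_cells), m_lo, m_hi)
    s_target = ((denom * pi * (1.0 - m) / m) - pi) / (2 * pi)
    js = np.arange(1, L) / L
    parts = [np.array([_H_MAIN + 0.6, _H_MAIN + 0.3])]
    valley_indices = [2]
    length = 2
    for i in range(n_cells):
        g = brentq(lambda x, st=s_target[i]: _flank_sum(x, log_js) - st,
                   _GAMMA_LO, _GAMMA_HI, xtol=1e-10)
        prof = pi * js ** g
        v = _H_MAIN * (1.0 + rng.uniform(-0.03, 0.03))
        parts.append(np.concatenate([[v], v + prof, [v + pi], v + prof[::-1]]))
        length += 2 * L
        valley_indices.append(length)
    parts.append([_H_MAIN, _H_MAIN + 0.3, _H_MAIN + 0.6])
    length += 3
    d = np.concatenate(parts)
    values = amplitude * (_P_MAIN + 1.0) - amplitude * d
    if values.size < n_samples:  # pad with a monotone, extremum-free ramp
        pad = values[-1] - amplitude * 0.1 * np.arange(1, n_samples - values.size + 1)
        values = np.concatenate([values, pad])
    return values[:n_samples], np.asarray(valley_indices, dtype=np.intp)


# --------------------------------------------------------------------------
# cardiac
# --------------------------------------------------------------------------

def gen_ibi(
    duration: float = 300.0,
    rr0: float = 0.9,
    a_lf: float = 0.0,
    a_hf: float = 0.0,
    f_lf: float = 0.10,
    f_hf: float = 0.25,
    noise_sd: float = 0.0,
    mms_shape: float = None,
    mms_scale: float = 0.0017,
    n_spikes: int = 300,
    rr_baseline: float = 1.1,
    rr_amplitude: float = 0.03,
    seed: int = 0,
    rng=None,
):
    """Synthetic inter-beat-interval series with ground truth.

    Two modes:

    * oscillatory (default): RR(t) = rr0 + a_lf sin(2 pi f_lf t)
      + a_hf sin(2 pi f_hf t) + Gaussian noise, with beats placed
      iteratively -- feeds the spectral (LF/HF) and Poincare analyses;
    * prescribed-MMS (``mms_shape`` given): the RR value sequence is an
      inverted spike train whose pipeline MMS amplitudes are iid
      Gamma(mms_shape, mms_scale) -- feeds parameter-recovery tests.  The RR
      values stay within [0.92, 1.10] s under the default baseline/amplitude,
      inside the physiologic artifact band.
    """
    rng = _rng_of(rng, seed)
    if mms_shape is not None:
        values, truth = mms_spike_train(
            n_spikes, mms_shape, mms_scale,
            baseline=rr_baseline, amplitude=rr_amplitude, rng=rng,
        )
        beat_times = np.concatenate([[0.0], np.cumsum(values)])
        return IBISeries(beat_times, values), truth
    if rr0 - abs(a_lf) - abs(a_hf) - 5.0 * noise_sd <= 0.05:
        raise InvalidInputError("parameters imply nonpositive RR intervals")
    beats = [0.0]
    t = 0.0
    while t < duration:
        rr = (rr0 + a_lf * np.sin(2 * np.pi * f_lf * t)
              + a_hf * np.sin(2 * np.pi * f_hf * t))
        if noise_sd:
            rr += rng.normal(0.0, noise_sd)
        if rr <= 0:
            raise InvalidInputError("drawn RR interval is nonpositive")
        t += rr
        beats.append(t)
    bt = np.asarray(beats)
    truth = {"rr0": rr0, "a_lf": a_lf, "a_hf": a_hf, "f_lf": f_lf,
             "f_hf": f_hf, "noise_sd": noise_sd, "n_beats": bt.size}
    return IBISeries(bt, np.diff(bt)), truth


def gen_ecg(
    beat_times,
    fs: float = 250.0,
    noise_sd: float = 0.0,
    snr_db: float = None,
    qrs_sigma: float = 0.010,
    amplitude: float = 1.0,
    duration: float = None,
    seed: int = 0,
    rng=None,
):
    """QRS-like ECG trace: a Mexican-hat template at each beat time (mV).

    The template ``(1 - u^2) exp(-u^2/2)`` with ``u = (t - beat)/qrs_sigma``
    peaks exactly at the beat time and has side lobes mimicking Q/S waves;
    its energy is concentrated near 20 Hz, inside the 5-30 Hz QRS band.
    Beats closer than the template support raise an error.  Additive white
    noise is set either directly (``noise_sd``) or via ``snr_db``, the
    signal-power-to-noise-power ratio in dB with signal power measured as
    the mean square of the clean trace.
    """
    rng = _rng_of(rng, seed)
    bt = np.asarray(beat_times, dtype=float)
    if bt.size and np.any(np.diff(bt) <= 10 * qrs_sigma):
        raise InvalidInputError("beats too close: QRS templates would overlap")
    t0 = (bt[0] - 0.5) if bt.size else 0.0  # pad so no template is edge-clipped
    if duration is None:
        duration = (bt[-1] + 0.5 - t0) if bt.size else 1.0
    n = int(round(duration * fs)) + 1
    t = t0 + np.arange(n) / fs
    v = np.zeros(n)
    for tb in bt:
        lo = max(0, int((tb - 6 * qrs_sigma - t0) * fs))
        hi = min(n, int((tb + 6 * qrs_sigma - t0) * fs) + 2)
        u = (t[lo:hi] - tb) / qrs_sigma
        v[lo:hi] += amplitude * (1.0 - u ** 2) * np.exp(-0.5 * u ** 2)
    if snr_db is not None:
        rms = float(np.sqrt(np.mean(v ** 2)))
        noise_sd = rms / 10.0 ** (snr_db / 20.0)
    if noise_sd:
        v = v + rng.normal(0.0, noise_sd, n)
    truth = {"beat_times": bt, "fs": fs, "noise_sd": noise_sd,
             "amplitude": amplitude}
    return UniformSeries.from_rate(v, fs, t0=t0, units="mV"), truth


# --------------------------------------------------------------------------
# kinematics
# --------------------------------------------------------------------------

#: Stylized per-task generator regimes: fluctuation amplitude (g) and target
#: Gamma parameters of the norm's MMS amplitudes.  More vigorous tasks get
#: larger fluctuations and noisier (higher-scale, lower-shape) signatures.
TASK_PROFILES = {
    "resting": {"amplitude": 0.004, "shape": 400.0, "scale": 0.0016},
    "pointing": {"amplitude": 0.012, "shape": 320.0, "scale": 0.0021},
    "walking": {"amplitude": 0.035, "shape": 250.0, "scale": 0.0027},
    "daily": {"amplitude": 0.020, "shape": 280.0, "scale": 0.0024},
    "sleep": {"amplitude": 0.003, "shape": 450.0, "scale": 0.0015},
}


def gen_imu(
    location: str = "pectoralis",
    task: str = "resting",
    n_spikes: int = 300,
    fs: float = 31.25,
    amplitude: float = None,
    mms_shape: float = None,
    mms_scale: float = None,
    direction=None,
    participant: str = "",
    seed: int = 0,
    rng=None,
):
    """Triaxial acceleration whose Euclidean norm is a prescribed spike train.

    The norm fluctuates just above 1 g (gravity-inclusive) along a fixed
    random unit direction; task profiles set the fluctuation amplitude and
    the target Gamma parameters unless overridden.  ``amplitude=0`` yields a
    constant 1-g gravity vector (a degenerate input for the MMS pipeline).
    """
    rng = _rng_of(rng, seed)
    prof = TASK_PROFILES[task] if task in TASK_PROFILES else TASK_PROFILES["resting"]
    amp = prof["amplitude"] if amplitude is None else amplitude
    a0 = prof["shape"] if mms_shape is None else mms_shape
    b0 = prof["scale"] if mms_scale is None else mms_scale
    if direction is None:
        u = rng.normal(size=3) + np.array([0.0, 0.0, 3.0])  # gravity-dominated
        u /= np.linalg.norm(u)
    else:
        u = np.asarray(direction, dtype=float)
        u /= np.linalg.norm(u)
    if amp == 0:
        norm = np.full(int(60 * fs), 1.0)
        truth = {"amplitude": 0.0}
    else:
        norm, truth = mms_spike_train(
            n_spikes, a0, b0, baseline=1.0 + amp * _P_MAIN, amplitude=amp, rng=rng
        )
    ts = np.arange(norm.size) / fs
    tri = TriaxialSeries(ts, norm * u[0], norm * u[1], norm * u[2],
                         location, task, participant, fs)
    truth.update({"direction": u, "task": task, "location": location})
    return tri, truth


# --------------------------------------------------------------------------
# face
# --------------------------------------------------------------------------

#: Per-region target Gamma parameters for facial speed MMS amplitudes.  The
#: noise-to-signal ratio (scale) is ordered V1 < V2 < V3 with a common mean.
FACE_REGION_TARGETS = {
    "V1": (655.0, 0.0011),
    "V2": (500.0, 0.00144),
    "V3": (380.0, 0.0019),
}


def _base_face(scale: float = 100.0) -> np.ndarray:
    """Stylized 68-landmark face in the iBUG layout, centered near origin."""
    pts = np.zeros((N_LANDMARKS, 2))
    th = np.linspace(np.pi, 2 * np.pi, 17)
    pts[0:17] = np.column_stack([np.cos(th), 1.3 * np.sin(th)])  # jaw 0-16
    bx = np.linspace(-0.7, -0.15, 5)
    pts[17:22] = np.column_stack([bx, 0.55 - 0.3 * (bx + 0.425) ** 2])  # brow L
    pts[22:27] = np.column_stack([-bx[::-1], 0.55 - 0.3 * (bx[::-1] + 0.425) ** 2])
    pts[27:31] = np.column_stack([np.zeros(4), np.linspace(0.4, -0.05, 4)])  # nose
    pts[31:36] = np.column_stack([np.linspace(-0.18, 0.18, 5), -0.15 * np.ones(5)])
    te = np.linspace(0, 2 * np.pi, 6, endpoint=False)
    pts[36:42] = np.column_stack([-0.42 + 0.14 * np.cos(te), 0.3 + 0.07 * np.sin(te)])
    pts[42:48] = np.column_stack([0.42 + 0.14 * np.cos(te), 0.3 + 0.07 * np.sin(te)])
    to = np.linspace(0, 2 * np.pi, 12, endpoint=False)
    pts[48:60] = np.column_stack([0.3 * np.cos(to), -0.55 + 0.15 * np.sin(to)])
    ti = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    pts[60:68] = np.column_stack([0.18 * np.cos(ti), -0.55 + 0.08 * np.sin(ti)])
    return pts * scale + np.array([320.0, 240.0])


def gen_face(
    n_frames: int = 150,
    frame_rate: float = 30.0,
    region_map: RegionMap = None,
    region_targets: dict = None,
    speed_amplitude: float = 1.5,
    emotion: str = None,
    seed: int = 0,
    rng=None,
):
    """Synthetic 68-landmark recording with region-controlled speed structure.

    Each landmark moves along a fixed random direction with a speed profile
    that is a spike train targeting its region's Gamma parameters; the
    direction of travel flips at each speed valley so landmarks stay near
    their base position.  For clips of at least ~270 frames the exact
    calibrated construction is used; shorter clips (e.g. the 150-frame,
    5-s emotion windows) fall back to an approximate train.
    ``speed_amplitude=0`` produces a static grid.

    The ground truth holds per-landmark target amplitudes; note that speeds
    re-estimated from positions via spline differentiation recover the
    targets only approximately (the construction is exact at the speed
    level, which :func:`gen_region_speeds` exposes directly).
    """
    rng = _rng_of(rng, seed)
    region_map = region_map or RegionMap.default()
    region_targets = region_targets or FACE_REGION_TARGETS
    base = _base_face()
    if speed_amplitude == 0:
        pos = np.repeat(base[None, :, :], n_frames, axis=0)
        return FaceGrid(pos, frame_rate, emotion), {"speed_amplitude": 0.0}
    exact = n_frames >= 270
    pos = np.empty((n_frames, N_LANDMARKS, 2))
    truth = {"exact": exact, "targets": {}, "mms": {}}
    for region, idx in region_map.regions.items():
        a0, b0 = region_targets.get(region, (500.0, 0.00144))
        truth["targets"][region] = (a0, b0)
        for j in idx:
            if exact:
                flank = 4
                n_sp = (n_frames - 21 - 4 * 2 * 2) // (2 * flank)
                speeds, tr = mms_spike_train(
                    n_sp, a0, b0, amplitude=speed_amplitude, flank=flank,
                    n_calibration=4, calibration_flank=2, rng=rng,
                )
                valleys = tr["valley_indices"]
                speeds = np.concatenate([
                    speeds,
                    np.full(max(0, n_frames - speeds.size), speeds[-1]
                            ) + 0.05 * speed_amplitude * np.arange(
                                max(0, n_frames - speeds.size)),
                ])[:n_frames]
                truth["mms"].setdefault(region, []).append(tr["mms"])
                truth["min_prominence"] = tr["min_prominence"]
            else:
                speeds, valleys = _approx_speed_train(
                    n_frames, a0, b0, speed_amplitude, rng
                )
                truth["min_prominence"] = 2.0 * speed_amplitude
            sign = np.ones(n_frames)
            flip = valleys[valleys < n_frames]
            marker = np.zeros(n_frames)
            marker[flip] = 1
            sign = (-1.0) ** np.cumsum(marker)
            u = rng.normal(size=2)
            u /= np.linalg.norm(u)
            disp = np.cumsum(sign * speeds) / frame_rate
            pos[:, j, :] = base[j] + disp[:, None] * u[None, :]
    return FaceGrid(pos, frame_rate, emotion), truth


def gen_region_speeds(
    n_landmarks: int = 8,
    n_spikes: int = 60,
    shape: float = 500.0,
    scale: float = 0.00144,
    frame_rate: float = 30.0,
    speed_amplitude: float = 1.0,
    seed: int = 0,
    rng=None,
):
    """Exact per-landmark speed trains for one region.

    Returns ``(speeds, truth)`` with ``speeds`` of shape
    (n_samples, n_landmarks); every landmark's pipeline MMS amplitudes are
    iid Gamma(shape, scale) draws, pooled in ``truth["mms"]``.
    """
    rng = _rng_of(rng, seed)
    cols = []
    pooled = []
    prominence = None
    for _ in range(n_landmarks):
        v, tr = mms_spike_train(n_spikes, shape, scale,
                                amplitude=speed_amplitude, rng=rng)
        cols.append(v)
        pooled.append(tr["mms"])
        prominence = tr["min_prominence"]
    speeds = np.column_stack(cols)
    truth = {"mms": np.concatenate(pooled), "shape": shape, "scale": scale,
             "min_prominence": prominence, "frame_rate": frame_rate}
    return speeds, truth


# --------------------------------------------------------------------------
# voice
# --------------------------------------------------------------------------

def gen_voice(
    duration: float = 8.0,
    fs: float = 44100.0,
    n_bursts: int = 12,
    band: int = 8,
    floor: float = 0.01,
    peak: float = 0.8,
    attack_time: float = 0.15,
    decay_time: float = 0.20,
    seed: int = 0,
    rng=None,
):
    """Burst-structured speech-like waveform (carrier at the band-8 center).

    The amplitude envelope is a low floor interrupted by ``n_bursts``
    attack/decay bursts with lightly jittered peaks; the carrier sits at the
    requested gammatone band's center frequency so the band's envelope
    reproduces the burst structure.  The default ramp times give a duty cycle
    above 50%, placing the session median amplitude on the burst ramps so
    the supra-median/sub-median segmentation rule isolates each burst
    exactly.  ``n_bursts=0`` yields silence.
    """
    rng = _rng_of(rng, seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    env = np.full(n, floor if n_bursts > 0 else 0.0)
    starts = []
    if n_bursts > 0:
        spacing = duration / (n_bursts + 1)
        if spacing <= attack_time + decay_time:
            raise InvalidInputError("bursts overlap: reduce n_bursts or ramp times")
        for k in range(1, n_bursts + 1):
            t0 = k * spacing + rng.uniform(-0.1, 0.1) * spacing
            pk = peak * (1.0 + rng.uniform(-0.1, 0.1))
            i0 = int(t0 * fs)
            na = int(attack_time * fs)
            nd = int(decay_time * fs)
            a_end = min(i0 + na, n)
            env[i0:a_end] = floor + (pk - floor) * np.arange(a_end - i0) / na
            d_end = min(i0 + na + nd, n)
            env[a_end:d_end] = pk - (pk - floor) * np.arange(d_end - a_end) / nd
            starts.append(t0)
    fc = float(erb_center_frequencies(fs)[band - 1])
    wave = env * np.sin(2 * np.pi * fc * t)
    truth = {"n_bursts": n_bursts, "burst_times": np.asarray(starts),
             "carrier": fc, "band": band}
    return UniformSeries.from_rate(wave, fs), truth


def gen_envelope(
    n_cycles: int = 200,
    fs: float = 500.0,
    slope_shape: float = 4.0,
    slope_scale: float = 0.5,
    v_low: float = 0.2,
    v_high: float = 1.0,
    seed: int = 0,
    rng=None,
):
    """Envelope with prescribed attack/decay slope distributions.

    Alternating linear ramps between ``v_low`` and ``v_high``; ramp durations
    are set so the absolute slopes are iid Gamma(slope_shape, slope_scale)
    draws, re-quantized to the sample grid.  The ground truth reports the
    grid-realized slopes (relative quantization error < 1% at the default
    rate), which the segmentation pipeline recovers exactly.
    """
    rng = _rng_of(rng, seed)
    da = v_high - v_low
    sa = rng.gamma(slope_shape, slope_scale, n_cycles)
    sd = rng.gamma(slope_shape, slope_scale, n_cycles)
    ka = np.maximum(2, np.round(fs * da / sa).astype(int))
    kd = np.maximum(2, np.round(fs * da / sd).astype(int))
    real_a = da * fs / ka
    real_d = da * fs / kd
    parts = [np.array([v_low + 0.10, v_low + 0.05])]  # lead-in: first trough is interior
    for i in range(n_cycles):
        parts.append(np.linspace(v_low, v_high, ka[i] + 1)[:-1])
        parts.append(np.linspace(v_high, v_low, kd[i] + 1)[:-1])
    parts.append(np.array([v_low, v_low + 0.05, v_low + 0.10]))
    values = np.concatenate(parts)
    env = EnvelopeSeries(UniformSeries.from_rate(values, fs), 8, 5600.0)
    truth = {"attack_slopes": real_a, "decay_slopes": real_d,
             "shape": slope_shape, "scale": slope_scale, "n_cycles": n_cycles}
    return env, truth
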