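"""Facial landmark kinematics with trigeminal parcellation.

A face is tracked as 68 landmarks per frame (iBUG numbering) at 30 Hz.  Each
frame is shape-normalized -- centroid moved to (0, 0), then isotropically
scaled so the standard deviation of the 68 landmark distances from the origin
is 1 -- which removes translation, camera-distance and head-size effects.
The grid is parcellated into the three trigeminal-nerve territories: V1
(ophthalmic: brows and eyes), V2 (maxillary: nose and upper jaw margin), V3
(mandibular: chin and mouth).  Landmark trajectories are smoothed with cubic
splines, differentiated to speed fields, and the pooled per-region speed
spikes are reduced to Gamma signatures, moment-space triangles, windowed
Earth-mover's-distance trajectories against reference expression signatures,
and pairwise transfer entropy between the regions.

Speeds are computed on the normalized coordinates, so all downstream
signatures are unitless and comparable across participants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.stats import wasserstein_distance

from .core import (
    GammaSignature,
    UniformSeries,
    empirical_gamma_fit,
    mms_pipeline,
)
from .errors import (
    DegenerateFitError,
    InsufficientDataError,
    InvalidInputError,
)

__all__ = [
    "N_LANDMARKS",
    "EMOTIONS",
    "DEFAULT_REGION_MAP",
    "FaceGrid",
    "RegionMap",
    "RegionSignature",
    "TriangleSignature",
    "normalize_face",
    "parcellate",
    "landmark_speeds",
    "region_signature",
    "triangle",
    "emd_trajectory",
    "transfer_entropy",
    "transfer_entropy_matrix",
]

N_LANDMARKS = 68
EMOTIONS = (
    "rest", "anger", "contempt", "disgust", "fear", "happiness", "sadness", "surprise",
)

#: Default landmark-to-region assignment on the standard 68-point iBUG grid.
#: This is a documented, configurable choice: V1 ophthalmic = eyebrows + eyes,
#: V2 maxillary = nose + upper jaw margin, V3 mandibular = chin + mouth.
DEFAULT_REGION_MAP = {
    "V1": tuple(range(17, 27)) + tuple(range(36, 48)),
    "V2": tuple(range(27, 36)) + tuple(range(0, 5)) + tuple(range(12, 17)),
    "V3": tuple(range(5, 12)) + tuple(range(48, 68)),
}


@dataclass(frozen=True)
class FaceGrid:
    """Frames x 68 landmark (x, y) positions with a frame rate and label."""

    positions: np.ndarray  # (n_frames, 68, 2)
    frame_rate: float = 30.0
    emotion: str = None

    def __post_init__(self):
        p = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", p)
        if p.ndim != 3 or p.shape[1] != N_LANDMARKS or p.shape[2] != 2:
            raise InvalidInputError("positions must have shape (n_frames, 68, 2)")
        if not self.frame_rate > 0:
            raise InvalidInputError("frame_rate must be positive")
        if self.emotion is not None and self.emotion not in EMOTIONS:
            raise InvalidInputError(f"emotion must be one of {EMOTIONS}")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def __len__(self) -> int:
        return self.n_frames


@dataclass(frozen=True)
class RegionMap:
    """Disjoint landmark-index sets covering all 68 indices."""

    regions: dict

    def __post_init__(self):
        seen = {}
        for name, idx in self.regions.items():
            if len(idx) == 0:
                raise InvalidInputError(f"region {name} is empty")
            for i in idx:
                if not 0 <= i < N_LANDMARKS:
                    raise InvalidInputError(f"landmark index {i} out of range")
                if i in seen:
                    raise InvalidInputError(
                        f"landmark {i} assigned to both {seen[i]} and {name}"
                    )
                seen[i] = name
        if len(seen) != N_LANDMARKS:
            missing = sorted(set(range(N_LANDMARKS)) - set(seen))
            raise InvalidInputError(f"region map misses landmarks {missing}")
        object.__setattr__(
            self, "regions", {k: tuple(v) for k, v in self.regions.items()}
        )

    @classmethod
    def default(cls) -> "RegionMap":
        return cls(dict(DEFAULT_REGION_MAP))

    def to_json_dict(self) -> dict:
        return {k: list(v) for k, v in self.regions.items()}

    @classmethod
    def from_json_dict(cls, d: dict) -> "RegionMap":
        return cls({k: tuple(int(i) for i in v) for k, v in d.items()})


@dataclass(frozen=True)
class RegionSignature:
    """Pooled Gamma signature of one facial region's micro-movement spikes."""

    region: str
    gamma: GammaSignature  # None when insufficient
    n_spikes: int
    insufficient: bool = False

    @property
    def moment_point(self) -> np.ndarray:
        """(Gamma mean, variance, skewness); marker size ~ kurtosis in plots."""
        if self.gamma is None:
            raise DegenerateFitError(f"region {self.region} has no valid fit")
        return self.gamma.moment_point


@dataclass(frozen=True)
class TriangleSignature:
    """V1/V2/V3 moment points as triangle vertices; area summarizes the
    micro-expression's spread in Gamma-moment space."""

    vertices: np.ndarray  # (3, 3)
    area: float


def normalize_face(grid: FaceGrid) -> FaceGrid:
    """Per-frame centroid alignment and isotropic scaling.

    After normalization each frame's landmark centroid is (0, 0) and the
    standard deviation of the 68 landmark Euclidean distances from the origin
    is exactly 1.  The map is idempotent and invariant to similarity
    transforms (translation + uniform scaling) of the input.
    """
    p = grid.positions.copy()
    centroid = p.mean(axis=1, keepdims=True)
    p -= centroid
    dist = np.linalg.norm(p, axis=2)  # (n_frames, 68)
    sd = dist.std(axis=1)
    if np.any(sd <= 0):
        raise InvalidInputError("degenerate frame: landmark distances have zero spread")
    p /= sd[:, None, None]
    return FaceGrid(p, grid.frame_rate, grid.emotion)


def parcellate(region_map: RegionMap, grid: FaceGrid) -> dict:
    """Split the grid into per-region trajectory bundles.

    Returns ``{region: positions (n_frames, n_region_landmarks, 2)}``; the
    landmark counts across regions sum to 68.
    """
    return {
        name: grid.positions[:, list(idx), :]
        for name, idx in region_map.regions.items()
    }


def landmark_speeds(grid: FaceGrid, smoothing: float = None) -> np.ndarray:
    """Spline-smoothed landmark speed fields.

    Each coordinate trajectory is fitted with a cubic smoothing spline
    (``smoothing`` is the roughness penalty lambda; None selects it by
    generalized cross-validation, 0 interpolates) and differentiated; the
    speed is the Euclidean norm of the velocity.  Returns an
    (n_frames, 68) array in normalized units (or pixels) per second.
    """
    if grid.n_frames < 5:
        raise InsufficientDataError("speed estimation requires >= 5 frames")
    t = np.arange(grid.n_frames) / grid.frame_rate
    speeds = np.empty((grid.n_frames, N_LANDMARKS))
    for j in range(N_LANDMARKS):
        vx = make_smoothing_spline(t, grid.positions[:, j, 0], lam=smoothing).derivative()(t)
        vy = make_smoothing_spline(t, grid.positions[:, j, 1], lam=smoothing).derivative()(t)
        speeds[:, j] = np.hypot(vx, vy)
    return speeds


def _pool_region_mms(
    speed_values: np.ndarray,
    frame_rate: float,
    min_separation: float,
    min_prominence: float,
    min_spikes_per_landmark: int,
):
    """Run the MMS pipeline per landmark column and pool the amplitudes."""
    pooled = []
    for j in range(speed_values.shape[1]):
        col = speed_values[:, j]
        if np.max(col) - np.min(col) < 1e-9:
            continue  # numerically frozen landmark (spline noise only)
        try:
            series = UniformSeries.from_rate(col, frame_rate)
            mms, _ = mms_pipeline(
                series, min_separation, min_prominence, min_spikes=min_spikes_per_landmark
            )
            pooled.append(mms.amplitudes)
        except (InsufficientDataError, DegenerateFitError, InvalidInputError):
            continue  # frozen or too-quiet landmark contributes no spikes
    return np.concatenate(pooled) if pooled else np.empty(0)


def region_signature(
    speeds: np.ndarray,
    region: str = "",
    frame_rate: float = 30.0,
    min_separation: float = 0.0,
    min_prominence: float = 0.0,
    min_spikes_per_landmark: int = 5,
    min_pooled_spikes: int = 20,
) -> RegionSignature:
    """Pooled MMS/Gamma signature of one region.

    ``speeds`` is (n_frames, n_region_landmarks).  Each landmark's speed
    series runs through the MMS pipeline independently (its own empirical
    Gamma mean), the normalized spike amplitudes are pooled order-free across
    landmarks, and a single Gamma distribution is fitted to the pool.  With
    fewer than ``min_pooled_spikes`` pooled spikes the signature is flagged
    insufficient instead of fitted.
    """
    speeds = np.atleast_2d(np.asarray(speeds, dtype=float))
    pooled = _pool_region_mms(
        speeds, frame_rate, min_separation, min_prominence, min_spikes_per_landmark
    )
    if pooled.size < min_pooled_spikes:
        return RegionSignature(region, None, int(pooled.size), insufficient=True)
    sig = empirical_gamma_fit(pooled)
    return RegionSignature(region, sig, int(pooled.size))


def triangle(sig_v1: RegionSignature, sig_v2: RegionSignature,
             sig_v3: RegionSignature) -> TriangleSignature:
    """Area of the 3-D triangle with vertices at the region moment points."""
    a = sig_v1.moment_point
    b = sig_v2.moment_point
    c = sig_v3.moment_point
    area = 0.5 * float(np.linalg.norm(np.cross(b - a, c - a)))
    return TriangleSignature(np.stack([a, b, c]), area)


def emd_trajectory(
    grid: FaceGrid,
    references: dict,
    region_map: RegionMap = None,
    window: int = 150,
    overlap: float = 0.5,
    min_window_spikes: int = 5,
    min_prominence: float = 0.0,
) -> dict:
    """Windowed Earth-mover's distances from a recording to reference signatures.

    The grid is normalized, parcellated, and cut into ``window``-frame
    segments advancing by ``window * (1 - overlap)`` frames.  Within each
    window and region the pooled MMS amplitude sample is compared, by 1-D EMD
    (the integral of the absolute CDF difference), against each reference
    amplitude sample (e.g. one per projected emotion).  Windows with fewer
    than ``min_window_spikes`` spikes are flagged unreliable (NaN distances).

    Returns ``{region: DataFrame(start_frame, n_spikes, unreliable,
    <one column per reference>)}``.
    """
    if not references:
        raise InvalidInputError("at least one reference sample is required")
    if grid.n_frames < window:
        raise InsufficientDataError("grid shorter than one window")
    region_map = region_map or RegionMap.default()
    norm = normalize_face(grid)
    speeds = landmark_speeds(norm)
    step = max(1, int(round(window * (1.0 - overlap))))
    starts = list(range(0, grid.n_frames - window + 1, step))
    out = {}
    for region, idx in region_map.regions.items():
        rows = []
        for s in starts:
            seg = speeds[s : s + window, list(idx)]
            pooled = _pool_region_mms(seg, grid.frame_rate, 0.0, min_prominence, 5)
            if pooled.size < min_window_spikes:
                rows.append({"start_frame": s, "n_spikes": int(pooled.size),
                             "unreliable": True,
                             **{k: np.nan for k in references}})
            else:
                rows.append({"start_frame": s, "n_spikes": int(pooled.size),
                             "unreliable": False,
                             **{k: wasserstein_distance(pooled, np.asarray(v, float))
                                for k, v in references.items()}})
        out[region] = pd.DataFrame(rows)
    return out


# --------------------------------------------------------------------------
# transfer entropy
# --------------------------------------------------------------------------

def _discretize(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency (quantile) binning; a constant series maps to bin 0."""
    x = np.asarray(x, dtype=float)
    if np.all(x == x[0]):
        return np.zeros(x.size, dtype=np.intp)
    edges = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right").astype(np.intp)


def _entropy_bits(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def transfer_entropy(
    x: np.ndarray,
    y: np.ndarray,
    lag: int = 1,
    bins: int = 3,
    bias_correction: bool = False,
) -> float:
    """Plug-in transfer entropy TE(X -> Y) in bits.

    TE(X->Y) = I(Y_{t+lag}; X_t | Y_t) estimated with equal-frequency binning:
    H(Y+,Y) + H(Y,X) - H(Y) - H(Y+,Y,X).  With ``bias_correction`` the
    Miller-Madow correction is applied to each entropy term.  The plug-in
    estimator is biased upward on independent data by roughly
    (q-1)^2 * q / (2 n ln 2) bits for q bins.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InvalidInputError("series must be aligned and equally long")
    if x.size <= lag + 1:
        raise InsufficientDataError("series too short for the requested lag")
    xd = _discretize(x, bins)
    yd = _discretize(y, bins)
    y_next, y_past, x_past = yd[lag:], yd[:-lag], xd[:-lag]
    q = bins

    def h(*cols):
        code = np.zeros(cols[0].size, dtype=np.intp)
        for c in cols:
            code = code * q + c
        val = _entropy_bits(code)
        if bias_correction:
            n_obs = cols[0].size
            k = np.unique(code).size
            val += (k - 1) / (2.0 * n_obs * np.log(2))
        return val

    te = h(y_next, y_past) + h(y_past, x_past) - h(y_past) - h(y_next, y_past, x_past)
    return float(max(te, 0.0) if not bias_correction else te)


def transfer_entropy_matrix(
    region_speeds: dict,
    lag: int = 1,
    bins: int = 3,
    bias_correction: bool = False,
) -> pd.DataFrame:
    """Pairwise TE (bits) among region speed series; diagonal is NaN.

    ``region_speeds`` maps region name -> 1-D series (e.g. the mean landmark
    speed of the region per frame).  The matrix is generally asymmetric:
    entry (row=i, col=j) is TE(i -> j), information flowing from i to j.
    """
    names = list(region_speeds)
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for src in names:
        for dst in names:
            if src == dst:
                continue
            mat.loc[src, dst] = transfer_entropy(
                region_speeds[src], region_speeds[dst], lag, bins, bias_correction
            )
    return mat
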