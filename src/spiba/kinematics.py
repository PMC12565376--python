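"""Triaxial accelerometry: Euclidean norm and per-task MMS/Gamma signatures.

Acceleration is recorded in g-units at each body location (pectoralis,
dominant arm, dominant leg); the triaxial components are collapsed to their
Euclidean norm (1 g = 9.8 m/s^2), left gravity-inclusive (resting norms sit
near 1 g), and run through the MMS/Gamma standardization.  Each (location,
task) recording thus contributes one point to a task parameter space spanned
by the Gamma noise-to-signal ratio and the center of position of the signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GammaSignature, UniformSeries, mms_pipeline
from .errors import InvalidInputError

__all__ = [
    "G_TO_SI",
    "LOCATIONS",
    "TASKS",
    "TriaxialSeries",
    "TaskSignature",
    "accel_norm",
    "imu_signature",
    "task_space",
]

#: gravitational conversion used throughout: 1 g is 9.8 m/s^2
G_TO_SI = 9.8

LOCATIONS = ("pectoralis", "arm", "leg")
TASKS = ("resting", "pointing", "walking", "daily", "sleep")


@dataclass(frozen=True)
class TriaxialSeries:
    """Uniformly sampled triaxial acceleration in g at a body location."""

    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    location: str
    task: str
    participant: str = ""
    sampling_rate: float = 31.25

    def __post_init__(self):
        for name in ("timestamps", "x", "y", "z"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.timestamps.size
        if not (self.x.size == self.y.size == self.z.size == n):
            raise InvalidInputError("timestamps and all three axes must be equally long")
        if self.location not in LOCATIONS:
            raise InvalidInputError(f"location must be one of {LOCATIONS}")
        if self.task not in TASKS:
            raise InvalidInputError(f"task must be one of {TASKS}")

    def __len__(self) -> int:
        return self.timestamps.size


@dataclass(frozen=True)
class TaskSignature:
    """Gamma signature plus center of position for one (location, task) record.

    ``center_of_position`` is the per-axis arithmetic mean of the raw
    acceleration over the task window (an explicit, documented reading of an
    otherwise loosely specified quantity); ``norm_mean`` is the mean of the
    Euclidean-norm signal in the same units.
    """

    location: str
    task: str
    gamma: GammaSignature
    center_of_position: tuple
    norm_mean: float
    participant: str = ""


def accel_norm(tri: TriaxialSeries, to_si: bool = False) -> UniformSeries:
    """Euclidean norm sqrt(x^2+y^2+z^2); ``to_si`` converts g to m/s^2."""
    norm = np.sqrt(tri.x ** 2 + tri.y ** 2 + tri.z ** 2)
    if to_si:
        return UniformSeries(tri.timestamps, norm * G_TO_SI, tri.sampling_rate, "m/s^2")
    return UniformSeries(tri.timestamps, norm, tri.sampling_rate, "g")


def imu_signature(
    tri: TriaxialSeries,
    min_separation: float = 0.0,
    min_prominence: float = 0.0,
    min_spikes: int = 20,
) -> TaskSignature:
    """MMS/Gamma signature of the acceleration norm for one recording."""
    norm = accel_norm(tri)
    _, sig = mms_pipeline(norm, min_separation, min_prominence, min_spikes)
    center = (float(np.mean(tri.x)), float(np.mean(tri.y)), float(np.mean(tri.z)))
    return TaskSignature(
        tri.location, tri.task, sig, center, float(np.mean(norm.values)), tri.participant
    )


def task_space(signatures) -> pd.DataFrame:
    """Tidy long-format table of task-space points, one row per signature.

    Duplicate (participant, location, task) keys are rejected; no statistics
    are computed here, the table feeds plotting and clustering downstream.
    """
    sigs = list(signatures)
    rows = []
    for s in sigs:
        rows.append({
            "participant": s.participant,
            "location": s.location,
            "task": s.task,
            "nsr": s.gamma.nsr,
            "shape": s.gamma.shape,
            "center_x": s.center_of_position[0],
            "center_y": s.center_of_position[1],
            "center_z": s.center_of_position[2],
            "norm_mean": s.norm_mean,
        })
    df = pd.DataFrame(
        rows,
        columns=["participant", "location", "task", "nsr", "shape",
                 "center_x", "center_y", "center_z", "norm_mean"],
    )
    if len(df) and df.duplicated(["participant", "location", "task"]).any():
        raise InvalidInputError("duplicate (participant, location, task) keys")
    return df
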