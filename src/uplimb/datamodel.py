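"""Core containers shared by every stage of the pipeline.

Coordinate convention: right-handed, millimetres. In the synthetic world the
global frame is X = subject's right, Y = up, Z = posterior (the depth camera
looks along +Z from in front of the subject). All real-world inputs are only
required to be self-consistent: joint angles are frame-relative and invariant
under a global rigid transform of the landmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Fixed channel order of every angle waveform: shoulder flexion/extension,
#: shoulder adduction/abduction, shoulder internal/external rotation, elbow
#: flexion/extension (degrees).
CHANNELS = ("FE", "AA", "IE", "EFE")

#: The four functional reaching tasks.
TASKS = (
    "t1_contralateral_shoulder",
    "t2_hand_to_mouth",
    "t3_comb_hair",
    "t4_back_pocket",
)

#: Depth-sensor skeleton landmarks the Kinect-style model needs.
KINECT_LANDMARKS = ("SS", "SM", "SL", "SR", "ER", "WR")

#: Marker-set registry for the marker-based (UWA) model. PUA1-3 / DUA1-3 are
#: the upper-arm / forearm technical cluster triads.
UWA_MARKERS = (
    "C7", "T10", "CLAV", "STRN", "PSH", "ASH", "ACR",
    "EM", "EL", "RS", "US",
    "PUA1", "PUA2", "PUA3", "DUA1", "DUA2", "DUA3", "CAR",
)

SOURCES = ("kinect", "mocap", "synthetic-truth")

_REGISTRY = {
    "kinect": set(KINECT_LANDMARKS),
    "mocap": set(UWA_MARKERS),
    "synthetic-truth": set(KINECT_LANDMARKS) | set(UWA_MARKERS),
}


class ValidationError(ValueError):
    """Raised when a container violates one of its invariants."""


class SingularGeometryError(ValueError):
    """Raised when landmark geometry degenerates (zero-length or collinear axes)."""


@dataclass
class LandmarkSeries:
    """Time-stamped 3D trajectories of named landmarks from one stream.

    Parameters
    ----------
    source : {"kinect", "mocap", "synthetic-truth"}
    rate_hz : float
        Nominal sampling rate (about 30 for the depth sensor, 100 for the
        optical system).
    positions : dict of str -> (T, 3) float array
        Per-landmark positions in millimetres, all of identical length T.
    times : (T,) float array
        Strictly increasing timestamps in seconds.
    """

    source: str
    rate_hz: float
    positions: dict
    times: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = {k: np.asarray(v, dtype=float) for k, v in self.positions.items()}
        self.validate()

    @property
    def names(self):
        return list(self.positions)

    @property
    def n_frames(self):
        return len(self.times)

    def validate(self):
        if self.source not in SOURCES:
            raise ValidationError(f"unknown source {self.source!r}")
        if not self.rate_hz > 0:
            raise ValidationError("rate_hz must be positive")
        if not self.positions:
            raise ValidationError("no landmarks")
        T = len(self.times)
        if T < 2:
            raise ValidationError("need at least 2 frames")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("timestamps must be strictly increasing")
        for name, arr in self.positions.items():
            if arr.shape != (T, 3):
                raise ValidationError(
                    f"landmark {name!r} has shape {arr.shape}, expected ({T}, 3)")
        allowed = _REGISTRY[self.source]
        unknown = [n for n in self.positions if n not in allowed]
        if unknown:
            raise ValidationError(
                f"unknown landmark name(s) for source {self.source!r}: {unknown}")
        if self.source == "kinect":
            missing = [n for n in KINECT_LANDMARKS if n not in self.positions]
            if missing:
                raise ValidationError(
                    f"kinect series missing required landmark(s): {missing}")

    def require(self, *names):
        missing = [n for n in names if n not in self.positions]
        if missing:
            raise ValidationError(f"missing landmark(s): {missing}")
        return tuple(self.positions[n] for n in names)


@dataclass
class AngleWaveform:
    """A 4-channel joint-angle time series [FE, AA, IE, EFE] in degrees."""

    values: np.ndarray
    rate_hz: Optional[float] = None
    normalized: bool = False
    task: Optional[str] = None
    subject_id: Optional[str] = None
    trial_id: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    @property
    def n_frames(self):
        return self.values.shape[0]

    def validate(self):
        if self.values.ndim != 2 or self.values.shape[1] != len(CHANNELS):
            raise ValidationError(
                f"values must be (T, {len(CHANNELS)}), got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("angle values must be finite")
        if self.normalized and self.values.shape[0] != 101:
            raise ValidationError("normalized waveforms must have T = 101")
        if self.task is not None and self.task not in TASKS:
            raise ValidationError(f"unknown task {self.task!r}")

    def channel(self, name):
        return self.values[:, CHANNELS.index(name)]

    def replace_values(self, values, *, rate_hz=None, normalized=None):
        """Copy of this waveform with new samples, keeping identity fields."""
        return AngleWaveform(
            values=values,
            rate_hz=self.rate_hz if rate_hz is None else rate_hz,
            normalized=self.normalized if normalized is None else normalized,
            task=self.task,
            subject_id=self.subject_id,
            trial_id=self.trial_id,
            meta=dict(self.meta),
        )


@dataclass
class SegmentFrame:
    """An origin plus a right-handed orthonormal axis set for a body segment.

    ``axes`` columns are the unit x, y, z axes expressed in the global frame.
    """

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        self.validate()

    def validate(self, tol=1e-9):
        if self.axes.shape != (3, 3):
            raise ValidationError("axes must be 3x3")
        err = np.abs(self.axes.T @ self.axes - np.eye(3)).max()
        if err > 1e-6:
            raise ValidationError(f"axes not orthonormal (max deviation {err:.2e})")
        if np.linalg.det(self.axes) < 0:
            raise ValidationError("axes must be right-handed (det +1)")

    @property
    def x(self):
        return self.axes[:, 0]

    @property
    def y(self):
        return self.axes[:, 1]

    @property
    def z(self):
        return self.axes[:, 2]


@dataclass
class TrialRecord:
    """One recorded trial: concurrent depth-sensor and optical streams."""

    subject_id: str
    task: str
    trial_id: str
    kinect_stream: LandmarkSeries
    mocap_stream: LandmarkSeries
    static_trial: Optional[LandmarkSeries] = None
    truth_angles: Optional[AngleWaveform] = None

    def __post_init__(self):
        if self.kinect_stream.source != "kinect":
            raise ValidationError("kinect_stream must have source 'kinect'")
        if self.mocap_stream.source != "mocap":
            raise ValidationError("mocap_stream must have source 'mocap'")
        if self.task not in TASKS:
            raise ValidationError(f"unknown task {self.task!r}")
        needs_cast = any(n not in self.mocap_stream.positions for n in ("EM", "EL", "RS", "US"))
        if needs_cast and self.static_trial is None:
            raise ValidationError(
                "static_trial required when dynamic mocap trials omit EM/EL/RS/US")


def unit(v, *, eps=1e-6, what="vector"):
    """Normalize the last axis; raise SingularGeometryError below ``eps`` mm."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n <= eps):
        raise SingularGeometryError(f"degenerate {what}: norm <= {eps}")
    return v / n
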