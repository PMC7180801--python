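"""Marker-based gold-standard kinematics (UWA-style upper-limb model).

Segment frames are built from the reflective markers, anatomical elbow/wrist
landmarks are reconstructed from rigid marker clusters (CAST), and shoulder +
elbow angles come from the same z-x-y Euler decomposition used by the
depth-sensor model, each segment expressed relative to its proximal segment.

Frames
------
Thorax: origin mid(C7, CLAV); y from mid(T10, STRN) up to mid(C7, CLAV);
z = normal of the (T10, C7, CLAV) plane, sign pointing to the subject's
right; x = y x z.
Upper arm: origin E = mid(EL, EM); y = unit(S - E) with S the centroid of the
available shoulder markers (PSH, ASH and optionally ACR); z = unit(y x (E - W)).
Forearm: origin W = mid(RS, US); y = unit(E - W); x = unit(y x (RS - US)) with
the anterior sign fixed at the first frame against the thorax x-axis and
temporal continuity afterwards; z = x x y.

The sign conventions marked "pointing laterally/anteriorly" are stated only
qualitatively by marker-based protocols; the deterministic disambiguation
rules above are this package's conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import (
    AngleWaveform,
    LandmarkSeries,
    SegmentFrame,
    SingularGeometryError,
    TrialRecord,
    ValidationError,
    unit,
)
from .kinect import (
    EPS_MM,
    MAX_SINGULAR_FRACTION,
    _upper_arm_z_carryforward,
    decompose_zxy,
    unwrap_deg,
)

#: CAST assignment: which cluster carries each reconstructed landmark.
CAST_CLUSTERS = {"EM": "PUA", "EL": "PUA", "RS": "DUA", "US": "DUA"}


@dataclass
class ElbowAngles:
    """Elbow angle triplet (degrees): flexion/extension, varus/valgus,
    internal/external rotation. Only EFE enters the 4-channel waveform."""

    EFE: np.ndarray
    EVV: np.ndarray
    EIE: np.ndarray


@dataclass
class CastCalibration:
    """Constant local coordinates of EM/EL/RS/US in their cluster frames."""

    local: dict  # landmark -> (3,) local coordinates (mm)

    def validate(self):
        for name, v in self.local.items():
            if name not in CAST_CLUSTERS:
                raise ValidationError(f"unexpected CAST landmark {name!r}")
            if not np.all(np.isfinite(v)):
                raise ValidationError(f"non-finite local coordinates for {name!r}")


def _cluster_frames(p1, p2, p3):
    """Technical frame of a 3-marker cluster, vectorized over time.

    marker1 = origin; x toward marker2; z = unit(x x (marker3 - marker1));
    y = z x x. Any consistent convention yields identical reconstructions.
    """
    x = unit(p2 - p1, eps=EPS_MM, what="cluster x-axis (marker1=marker2)")
    z = unit(np.cross(x, p3 - p1), eps=EPS_MM, what="cluster plane (collinear markers)")
    y = np.cross(z, x)
    axes = np.stack([x, y, z], axis=-1)
    return p1, axes


def thorax_frame_uwa(C7, T10, CLAV, STRN, right_hint=None) -> SegmentFrame:
    """Thorax frame from the four trunk markers (single frame).

    ``right_hint`` is a vector with a positive component toward the subject's
    right used to fix the lateral sign of z; defaults to global +x.
    """
    C7, T10, CLAV, STRN = (np.asarray(p, dtype=float) for p in (C7, T10, CLAV, STRN))
    o_thorax = 0.5 * (C7 + CLAV)
    o_torso = 0.5 * (T10 + STRN)
    y = unit(o_thorax - o_torso, eps=EPS_MM, what="thorax y-axis")
    normal = np.cross(C7 - T10, CLAV - T10)
    z = unit(normal, eps=EPS_MM, what="thorax plane (collinear T10/C7/CLAV)")
    hint = np.array([1.0, 0.0, 0.0]) if right_hint is None else np.asarray(right_hint, float)
    if np.dot(z, hint) < 0:
        z = -z
    x = unit(np.cross(y, z), eps=EPS_MM, what="thorax x-axis")
    z = np.cross(x, y)  # re-orthogonalize
    return SegmentFrame(origin=o_thorax, axes=np.column_stack([x, y, z]))


def joint_centers_uwa(PSH, ASH, ACR=None, EL=None, EM=None, RS=None, US=None):
    """Shoulder, elbow, wrist joint centers from the arm markers."""
    shoulder_markers = [m for m in (PSH, ASH, ACR) if m is not None]
    if len(shoulder_markers) < 2:
        raise ValidationError("need at least two shoulder markers (PSH/ASH/ACR)")
    S = np.mean([np.asarray(m, dtype=float) for m in shoulder_markers], axis=0)
    if EL is None or EM is None or RS is None or US is None:
        raise ValidationError("EL/EM/RS/US required (measured or CAST-reconstructed)")
    E = 0.5 * (np.asarray(EL, float) + np.asarray(EM, float))
    W = 0.5 * (np.asarray(RS, float) + np.asarray(US, float))
    return S, E, W


def upper_arm_frame_uwa(S, E, W) -> SegmentFrame:
    """Upper-arm frame from the joint centers (same construction as the
    depth-sensor model with S, E, W in place of SR, ER, WR)."""
    S, E, W = (np.asarray(p, dtype=float) for p in (S, E, W))
    y = unit(S - E, eps=EPS_MM, what="upper-arm y-axis (S-E)")
    z = unit(np.cross(y, E - W), eps=EPS_MM,
             what="upper-arm z-axis (arm fully extended)")
    x = unit(np.cross(y, z), eps=EPS_MM, what="upper-arm x-axis")
    return SegmentFrame(origin=E, axes=np.column_stack([x, y, z]))


def forearm_frame_uwa(E, W, RS, US, anterior_hint=None) -> SegmentFrame:
    """Forearm frame; ``anterior_hint`` fixes the x-axis sign (default +x)."""
    E, W, RS, US = (np.asarray(p, dtype=float) for p in (E, W, RS, US))
    y = unit(E - W, eps=EPS_MM, what="forearm y-axis (E-W)")
    x = unit(np.cross(y, RS - US), eps=EPS_MM,
             what="forearm x-axis (styloids degenerate)")
    if anterior_hint is not None and np.dot(x, np.asarray(anterior_hint, float)) < 0:
        x = -x
    z = np.cross(x, y)
    return SegmentFrame(origin=W, axes=np.column_stack([x, y, z]))


def cast_calibrate(static: LandmarkSeries) -> CastCalibration:
    """Fit constant cluster-local coordinates of EM/EL/RS/US from a static trial."""
    pua = static.require("PUA1", "PUA2", "PUA3")
    dua = static.require("DUA1", "DUA2", "DUA3")
    frames = {"PUA": _cluster_frames(*pua), "DUA": _cluster_frames(*dua)}
    local = {}
    for name, cluster in CAST_CLUSTERS.items():
        (lm,) = static.require(name)
        origin, axes = frames[cluster]
        rel = lm - origin
        loc = np.einsum("tij,ti->tj", axes, rel)  # axes^T . rel per frame
        local[name] = loc.mean(axis=0)
    cal = CastCalibration(local=local)
    cal.validate()
    return cal


def cast_reconstruct(dynamic: LandmarkSeries, cal: CastCalibration) -> LandmarkSeries:
    """Append EM/EL/RS/US reconstructed from the cluster technical frames."""
    pua = dynamic.require("PUA1", "PUA2", "PUA3")
    dua = dynamic.require("DUA1", "DUA2", "DUA3")
    frames = {"PUA": _cluster_frames(*pua), "DUA": _cluster_frames(*dua)}
    positions = dict(dynamic.positions)
    for name, cluster in CAST_CLUSTERS.items():
        if name in positions:
            continue  # measured directly; keep
        origin, axes = frames[cluster]
        positions[name] = origin + np.einsum("tij,j->ti", axes, cal.local[name])
    return LandmarkSeries(source=dynamic.source, rate_hz=dynamic.rate_hz,
                          positions=positions, times=dynamic.times,
                          meta=dict(dynamic.meta))


def kinematics_uwa(trial, static=None, return_elbow_triplet=False):
    """Gold-standard angle waveform [FE, AA, IE, EFE] for one trial.

    ``trial`` is a TrialRecord, or a mocap LandmarkSeries combined with an
    optional ``static`` trial. EM/EL/RS/US are CAST-reconstructed from the
    static trial when the dynamic stream omits them. Elbow varus/valgus and
    internal/external rotation are computed by the decomposition but excluded
    from the 4-channel waveform; request them with
    ``return_elbow_triplet=True``.
    """
    if isinstance(trial, LandmarkSeries):
        dyn = trial
        task = subject_id = trial_id = None
    else:
        dyn = trial.mocap_stream
        static = trial.static_trial
        task, subject_id, trial_id = trial.task, trial.subject_id, trial.trial_id
    if any(n not in dyn.positions for n in CAST_CLUSTERS):
        if static is None:
            raise ValidationError("missing elbow/wrist markers and no static trial")
        cal = cast_calibrate(static)
        dyn = cast_reconstruct(dyn, cal)

    C7, T10, CLAV, STRN = dyn.require("C7", "T10", "CLAV", "STRN")
    PSH, ASH = dyn.require("PSH", "ASH")
    ACR = dyn.positions.get("ACR")
    EL, EM, RS, US = dyn.require("EL", "EM", "RS", "US")

    shoulder_markers = [PSH, ASH] + ([ACR] if ACR is not None else [])
    S = np.mean(shoulder_markers, axis=0)
    E = 0.5 * (EL + EM)
    W = 0.5 * (RS + US)

    # thorax, lateral sign from mid-shoulder -> right-shoulder direction
    o_thorax = 0.5 * (C7 + CLAV)
    o_torso = 0.5 * (T10 + STRN)
    ty = unit(o_thorax - o_torso, eps=EPS_MM, what="thorax y-axis")
    tz = unit(np.cross(C7 - T10, CLAV - T10), eps=EPS_MM,
              what="thorax plane (collinear T10/C7/CLAV)")
    lateral_hint = S - o_thorax
    sign = np.where(np.einsum("tj,tj->t", tz, lateral_hint) < 0, -1.0, 1.0)
    tz = tz * sign[:, None]
    tx = unit(np.cross(ty, tz), eps=EPS_MM, what="thorax x-axis")
    tz = np.cross(tx, ty)

    # upper arm
    uy = unit(S - E, eps=EPS_MM, what="upper-arm y-axis")
    uz, singular = _upper_arm_z_carryforward(uy, E - W)
    T = dyn.n_frames
    if singular.sum() > MAX_SINGULAR_FRACTION * T:
        raise SingularGeometryError(
            f"unusable trial: {int(singular.sum())}/{T} frames fully extended")
    ux = unit(np.cross(uy, uz), eps=EPS_MM, what="upper-arm x-axis")

    # forearm: anterior sign fixed at the first frame, continuity afterwards
    fy = unit(E - W, eps=EPS_MM, what="forearm y-axis")
    fx = unit(np.cross(fy, RS - US), eps=EPS_MM, what="forearm x-axis")
    if np.dot(fx[0], tx[0]) < 0:
        fx = -fx
    flips = np.einsum("tj,tj->t", fx[1:], fx[:-1]) < 0
    flip_state = np.cumsum(flips) % 2  # odd cumulative flip count -> negate
    fx[1:][flip_state == 1] *= -1.0
    fz = np.cross(fx, fy)

    Ct = np.stack([tx, ty, tz], axis=2)
    Cu = np.stack([ux, uy, uz], axis=2)
    Cf = np.stack([fx, fy, fz], axis=2)

    R_shoulder = np.einsum("tij,tik->tjk", Ct, Cu)
    fe, aa, ie, _ = decompose_zxy(R_shoulder)

    R_elbow = np.einsum("tij,tik->tjk", Cu, Cf)
    efe, evv, eie, _ = decompose_zxy(R_elbow)

    values = unwrap_deg(np.column_stack([fe, aa, ie, efe]))
    wf = AngleWaveform(
        values=values,
        rate_hz=dyn.rate_hz,
        task=task,
        subject_id=subject_id,
        trial_id=trial_id,
        meta={"singular_frames": np.nonzero(singular)[0].tolist(),
              "times": dyn.times.copy()},
    )
    if return_elbow_triplet:
        return wf, ElbowAngles(EFE=values[:, 3],
                               EVV=unwrap_deg(evv[:, None])[:, 0],
                               EIE=unwrap_deg(eie[:, None])[:, 0])
    return wf
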