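"""Depth-sensor kinematic model: shoulder FE/AA/IE and elbow FE from the six
skeleton landmarks (SpineShoulder, SpineMid, ShoulderLeft, ShoulderRight,
ElbowRight, WristRight).

Segment frames
--------------
Thorax: origin SS, y = unit(SS-SM), z = unit(y x (SR-SL)), x = unit(y x z).
Upper arm: origin ER, y = unit(SR-ER), z = unit(y x (ER-WR)), x = unit(y x z).

Shoulder angles come from R = C_thorax^T . C_upperarm decomposed as the
z-x-y sequence R = Rz(FE) . Rx(AA) . Ry(IE):

    AA = asin(R[2,1]),  IE = atan2(-R[2,0], R[2,2]),  FE = atan2(-R[0,1], R[1,1])

Elbow flexion is the angle between the upper-arm long axis and the
elbow-to-wrist vector. Under the default ``flexion`` convention full
extension reads 0 deg; ``raw-acos`` exposes the literal arccos value
(180 deg at full extension).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import (
    AngleWaveform,
    LandmarkSeries,
    SegmentFrame,
    SingularGeometryError,
    ValidationError,
    unit,
)

EPS_MM = 1e-6
#: |AA| within this many degrees of 90 triggers the gimbal-lock branch.
GIMBAL_MARGIN_DEG = 1.0
#: Fraction of singular (fully extended arm) frames above which a trial is unusable.
MAX_SINGULAR_FRACTION = 0.2


@dataclass
class ShoulderAngles:
    """Shoulder Euler angles (degrees) plus a gimbal-lock flag."""

    FE: float
    AA: float
    IE: float
    gimbal_flag: bool = False


def _cross(a, b):
    return np.cross(a, b)


def thorax_frame_kinect(SS, SM, SL, SR) -> SegmentFrame:
    """Thorax segment frame from the four trunk landmarks."""
    SS, SM, SL, SR = (np.asarray(p, dtype=float) for p in (SS, SM, SL, SR))
    y = unit(SS - SM, eps=EPS_MM, what="thorax y-axis (SS-SM)")
    z = unit(_cross(y, SR - SL), eps=EPS_MM,
             what="thorax z-axis (y x (SR-SL) collinear)")
    x = unit(_cross(y, z), eps=EPS_MM, what="thorax x-axis")
    return SegmentFrame(origin=SS, axes=np.column_stack([x, y, z]))


def upper_arm_frame_kinect(SR, ER, WR) -> SegmentFrame:
    """Upper-arm segment frame; singular when the arm is fully extended."""
    SR, ER, WR = (np.asarray(p, dtype=float) for p in (SR, ER, WR))
    y = unit(SR - ER, eps=EPS_MM, what="upper-arm y-axis (SR-ER)")
    z = unit(_cross(y, ER - WR), eps=EPS_MM,
             what="upper-arm z-axis (arm fully extended)")
    x = unit(_cross(y, z), eps=EPS_MM, what="upper-arm x-axis")
    return SegmentFrame(origin=ER, axes=np.column_stack([x, y, z]))


def compose_zxy(fe_deg, aa_deg, ie_deg):
    """Rotation matrix Rz(FE) . Rx(AA) . Ry(IE) from degrees (vectorized)."""
    a, b, c = (np.deg2rad(np.asarray(v, dtype=float)) for v in (fe_deg, aa_deg, ie_deg))
    sa, ca = np.sin(a), np.cos(a)
    sb, cb = np.sin(b), np.cos(b)
    sc, cc = np.sin(c), np.cos(c)
    R = np.empty(np.broadcast(sa, sb, sc).shape + (3, 3))
    R[..., 0, 0] = ca * cc - sa * sb * sc
    R[..., 0, 1] = -sa * cb
    R[..., 0, 2] = ca * sc + sa * sb * cc
    R[..., 1, 0] = sa * cc + ca * sb * sc
    R[..., 1, 1] = ca * cb
    R[..., 1, 2] = sa * sc - ca * sb * cc
    R[..., 2, 0] = -cb * sc
    R[..., 2, 1] = sb
    R[..., 2, 2] = cb * cc
    return R


def decompose_zxy(R):
    """Inverse of :func:`compose_zxy` (degrees). Vectorized over leading axes.

    Returns ``(FE, AA, IE, gimbal_flag)``. Within ``GIMBAL_MARGIN_DEG`` of
    AA = +/-90 deg only FE+IE (or FE-IE) is determined; the convention here
    zeroes IE and assigns the whole outer rotation to FE.
    """
    R = np.asarray(R, dtype=float)
    r21 = np.clip(R[..., 2, 1], -1.0, 1.0)
    aa = np.arcsin(r21)
    ie = np.arctan2(-R[..., 2, 0], R[..., 2, 2])
    fe = np.arctan2(-R[..., 0, 1], R[..., 1, 1])
    gimbal = np.abs(r21) > np.cos(np.deg2rad(GIMBAL_MARGIN_DEG))
    if np.any(gimbal):
        fe_lock = np.arctan2(R[..., 1, 0], R[..., 0, 0])
        fe = np.where(gimbal, fe_lock, fe)
        ie = np.where(gimbal, 0.0, ie)
    return (np.rad2deg(fe), np.rad2deg(aa), np.rad2deg(ie), gimbal)


def shoulder_angles(thorax: SegmentFrame, upper_arm: SegmentFrame) -> ShoulderAngles:
    """Shoulder Euler angles from the two segment frames."""
    R = thorax.axes.T @ upper_arm.axes
    fe, aa, ie, gimbal = decompose_zxy(R)
    return ShoulderAngles(FE=float(fe), AA=float(aa), IE=float(ie),
                          gimbal_flag=bool(gimbal))


def elbow_angle(SR, ER, WR, convention="flexion") -> float:
    """Elbow angle in degrees.

    ``flexion`` (default): 0 deg at full extension, increasing with flexion.
    ``raw-acos``: the literal angle between the upper-arm long axis (elbow to
    shoulder) and the elbow-to-wrist vector (180 deg at full extension).
    """
    SR, ER, WR = (np.asarray(p, dtype=float) for p in (SR, ER, WR))
    y = unit(SR - ER, eps=EPS_MM, what="upper-arm axis (SR-ER)")
    v = unit(WR - ER, eps=EPS_MM, what="forearm vector (WR-ER)")
    raw = np.degrees(np.arccos(np.clip(np.dot(y, v), -1.0, 1.0)))
    if convention == "raw-acos":
        return float(raw)
    if convention == "flexion":
        return float(180.0 - raw)
    raise ValueError(f"unknown elbow convention {convention!r}")


def unwrap_deg(values):
    """Per-channel unwrap: remove +/-360 deg jumps, first frame in (-180, 180]."""
    values = np.asarray(values, dtype=float)
    first = (values[0] + 180.0) % 360.0 - 180.0
    out = np.rad2deg(np.unwrap(np.deg2rad(values), axis=0))
    return out + (first - out[0])


def _upper_arm_z_carryforward(y, er_wr):
    """Vectorized upper-arm z over time with carry of the last valid frame.

    ``y``: (T,3) unit long axis; ``er_wr``: (T,3) elbow-to-wrist (reversed).
    Returns (z, singular_mask).
    """
    raw = np.cross(y, er_wr)
    norms = np.linalg.norm(raw, axis=1)
    scale = np.linalg.norm(er_wr, axis=1)
    singular = norms <= np.maximum(EPS_MM, 1e-4 * scale)
    z = np.zeros_like(raw)
    ok = ~singular
    z[ok] = raw[ok] / norms[ok, None]
    if not np.any(ok):
        raise SingularGeometryError("arm fully extended in every frame")
    # forward fill, then backward fill the leading gap
    last = None
    for t in range(len(z)):
        if singular[t]:
            if last is not None:
                z[t] = last
        else:
            last = z[t]
    first_ok = int(np.argmax(ok))
    z[:first_ok] = z[first_ok]
    return z, singular


def kinematics_kinect(series: LandmarkSeries, elbow_convention="flexion") -> AngleWaveform:
    """Per-frame angles [FE, AA, IE, EFE] from a depth-sensor stream.

    Frames where the arm is fully extended (upper-arm z undefined) reuse the
    neighbouring valid z-axis; their indices are listed in
    ``meta["singular_frames"]``. More than 20% singular frames is an error.
    """
    if series.source not in ("kinect", "synthetic-truth"):
        raise ValidationError("kinematics_kinect expects a kinect-source series")
    SS, SM, SL, SR, ER, WR = series.require("SS", "SM", "SL", "SR", "ER", "WR")
    T = series.n_frames

    ty = unit(SS - SM, eps=EPS_MM, what="thorax y-axis")
    tz = unit(np.cross(ty, SR - SL), eps=EPS_MM, what="thorax z-axis")
    tx = unit(np.cross(ty, tz), eps=EPS_MM, what="thorax x-axis")

    uy = unit(SR - ER, eps=EPS_MM, what="upper-arm y-axis")
    uz, singular = _upper_arm_z_carryforward(uy, ER - WR)
    n_sing = int(singular.sum())
    if n_sing > MAX_SINGULAR_FRACTION * T:
        raise SingularGeometryError(
            f"unusable trial: {n_sing}/{T} frames have a fully extended arm")
    ux = unit(np.cross(uy, uz), eps=EPS_MM, what="upper-arm x-axis")

    # R[t] = C_thorax[t]^T . C_upperarm[t]
    Ct = np.stack([tx, ty, tz], axis=2)
    Cu = np.stack([ux, uy, uz], axis=2)
    R = np.einsum("tij,tik->tjk", Ct, Cu)
    fe, aa, ie, _ = decompose_zxy(R)

    v = unit(WR - ER, eps=EPS_MM, what="forearm vector")
    raw = np.degrees(np.arccos(np.clip(np.einsum("tj,tj->t", uy, v), -1.0, 1.0)))
    if elbow_convention == "flexion":
        efe = 180.0 - raw
    elif elbow_convention == "raw-acos":
        efe = raw
    else:
        raise ValueError(f"unknown elbow convention {elbow_convention!r}")

    values = unwrap_deg(np.column_stack([fe, aa, ie, efe]))
    return AngleWaveform(
        values=values,
        rate_hz=series.rate_hz,
        meta={"singular_frames": np.nonzero(singular)[0].tolist(),
              "times": series.times.copy(),
              "elbow_convention": elbow_convention},
    )
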