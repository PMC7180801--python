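"""File formats: long-format landmark CSV (canonical), TRC (read-only), and
JSON export of angle waveforms.

The CSV dialect is ``time,landmark,x,y,z`` with seconds and millimetres; one
row per landmark per frame. Every frame must contain every landmark.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from .datamodel import AngleWaveform, CHANNELS, LandmarkSeries, ValidationError

_CSV_COLUMNS = ["time", "landmark", "x", "y", "z"]


def write_landmark_csv(series: LandmarkSeries, path) -> str:
    """Write a LandmarkSeries in the canonical long CSV dialect."""
    if not series.positions:
        raise ValidationError("refusing to write a series with no landmarks")
    names = series.names
    T = series.n_frames
    frames = []
    for name in names:
        arr = series.positions[name]
        frames.append(pd.DataFrame({
            "time": series.times,
            "landmark": name,
            "x": arr[:, 0], "y": arr[:, 1], "z": arr[:, 2],
        }))
    df = pd.concat(frames, ignore_index=True).sort_values(
        ["time", "landmark"], kind="stable")
    with open(path, "w") as fh:
        fh.write(f"# source={series.source} rate_hz={series.rate_hz!r}\n")
        df.to_csv(fh, index=False, float_format="%.9f")
    return str(path)


def read_landmark_csv(path, source=None, rate_hz=None) -> LandmarkSeries:
    """Read the canonical long CSV dialect into a validated LandmarkSeries.

    ``source``/``rate_hz`` override the header comment when given (files from
    other tools may lack it).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    header_meta = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    header_meta[k] = v
            df = pd.read_csv(fh)
        else:
            df = pd.read_csv(path)
    missing_cols = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"CSV missing column(s) {missing_cols}")
    source = source or header_meta.get("source")
    if source is None:
        raise ValidationError("source not given and not present in the file header")
    if rate_hz is None:
        rate_hz = float(header_meta.get("rate_hz", "nan"))
        if not np.isfinite(rate_hz):
            raise ValidationError("rate_hz not given and not present in the file header")

    times = np.array(sorted(df["time"].unique()), dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValidationError("non-monotonic timestamps")
    positions = {}
    for name, group in df.groupby("landmark", sort=False):
        g = group.sort_values("time", kind="stable")
        if len(g) != len(times) or not np.array_equal(g["time"].to_numpy(dtype=float), times):
            raise ValidationError(
                f"landmark {name!r} does not cover every frame (ragged frame counts)")
        positions[str(name)] = g[["x", "y", "z"]].to_numpy(dtype=float)
    return LandmarkSeries(source=source, rate_hz=float(rate_hz),
                          positions=positions, times=times)


def read_trc(path) -> LandmarkSeries:
    """Read a standard TRC marker file into a mocap LandmarkSeries (mm)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 6:
        raise ValidationError("malformed TRC: too short")
    keys = lines[1].split("\t")
    vals = lines[2].split("\t")
    header = dict(zip(keys, vals))
    try:
        rate = float(header["DataRate"])
        n_markers = int(header["NumMarkers"])
        units = header["Units"].strip()
    except (KeyError, ValueError) as exc:
        raise ValidationError(f"malformed TRC header: {exc}") from exc
    if units not in ("mm", "m"):
        raise ValidationError(f"unsupported TRC units {units!r} (expected mm or m)")
    scale = 1.0 if units == "mm" else 1000.0
    marker_names = [n for n in lines[3].split("\t")[2:] if n.strip()]
    if len(marker_names) != n_markers:
        raise ValidationError("TRC marker-name count disagrees with NumMarkers")
    rows = []
    for line in lines[5:]:
        if not line.strip():
            continue
        rows.append(line.split("\t"))
    times = np.array([float(r[1]) for r in rows])
    data = np.array([[float(x) for x in r[2:2 + 3 * n_markers]] for r in rows])
    positions = {name: data[:, 3 * i:3 * i + 3] * scale
                 for i, name in enumerate(marker_names)}
    return LandmarkSeries(source="mocap", rate_hz=rate, positions=positions,
                          times=times)


def write_waveform_json(wf: AngleWaveform, path) -> str:
    doc = {
        "channels": list(CHANNELS),
        "values": wf.values.tolist(),
        "rate_hz": wf.rate_hz,
        "normalized": wf.normalized,
        "task": wf.task,
        "subject_id": wf.subject_id,
        "trial_id": wf.trial_id,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
    return str(path)


def read_waveform_json(path) -> AngleWaveform:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("channels") != list(CHANNELS):
        raise ValidationError(f"unexpected channel list {doc.get('channels')}")
    return AngleWaveform(
        values=np.asarray(doc["values"], dtype=float),
        rate_hz=doc.get("rate_hz"),
        normalized=bool(doc.get("normalized", False)),
        task=doc.get("task"),
        subject_id=doc.get("subject_id"),
        trial_id=doc.get("trial_id"),
    )
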