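"""Readers and writers for the mocap text formats the pipeline touches.

TRC (tab-delimited marker trajectories, 5 header lines, mm or m units) and
MOT/STO (tab-delimited time-series tables with a ``name``/``nRows``/
``nColumns``/``inDegrees``/``endheader`` preamble).  All round-trips are
lossless at 1e-9 and truncated files are rejected loudly.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import ExternalLoads, LoadChannel
from .errors import ParseError
from .kinematics import MarkerTrajectories

_AXES = ("x", "y", "z")

# Column-name convention mapping a GRF prefix onto ExternalLoads fields:
# {prefix}_force_v{x,y,z}, {prefix}_force_p{x,y,z}, {prefix}_torque_{x,y,z}.
DEFAULT_GRF_PREFIXES = {"ground_force_r": "foot_r", "ground_force_l": "foot_l"}


# ---------------------------------------------------------------------------
# TRC


def read_trc(path) -> MarkerTrajectories:
    """Read a TRC marker-trajectory file (positions converted to meters;
    blank cells become masked samples)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 6:
        raise ParseError("TRC file has fewer than 6 lines", line=len(lines))
    meta_keys = lines[1].split("\t")
    meta_vals = lines[2].split("\t")
    meta = dict(zip(meta_keys, meta_vals))
    try:
        rate = float(meta["DataRate"])
        n_frames = int(meta["NumFrames"])
        n_markers = int(meta["NumMarkers"])
        units = meta["Units"].strip().lower()
    except (KeyError, ValueError) as exc:
        raise ParseError(f"malformed TRC header: {exc}", line=3) from None
    if units not in ("mm", "m"):
        raise ParseError(f"unsupported TRC units {units!r}", line=3)
    to_m = 0.001 if units == "mm" else 1.0
    labels = lines[3].rstrip("\n").split("\t")
    names = [s.strip() for s in labels[2:] if s.strip()]
    if len(names) != n_markers:
        raise ParseError(
            f"label row names {len(names)} markers, header says {n_markers}",
            line=4,
        )
    n_cols = 2 + 3 * n_markers
    data_lines = [ln for ln in lines[5:] if ln.strip()]
    if len(data_lines) != n_frames:
        raise ParseError(
            f"found {len(data_lines)} data rows, header declares {n_frames}"
        )
    times = np.empty(n_frames)
    pos = np.full((n_frames, n_markers, 3), np.nan)
    for r, ln in enumerate(data_lines):
        cells = ln.split("\t")
        if len(cells) < 2 or len(cells) > n_cols:
            raise ParseError(
                f"row has {len(cells)} columns, expected {n_cols}", line=6 + r
            )
        cells = cells + [""] * (n_cols - len(cells))
        try:
            times[r] = float(cells[1])
            for m in range(n_markers):
                trip = cells[2 + 3 * m : 5 + 3 * m]
                if all(c.strip() for c in trip):
                    pos[r, m] = [float(c) for c in trip]
        except ValueError as exc:
            raise ParseError(str(exc), line=6 + r) from None
    return MarkerTrajectories(
        times=times, rate=rate, names=tuple(names), positions=pos * to_m
    )


def write_trc(trajectories: MarkerTrajectories, path, *, units: str = "mm") -> None:
    """Write a TRC file; masked samples become blank cells."""
    units = units.lower()
    if units not in ("mm", "m"):
        raise ParseError(f"unsupported TRC units {units!r}")
    scale = 1000.0 if units == "mm" else 1.0
    t = trajectories
    n_frames, n_markers = t.positions.shape[:2]
    lines = [
        f"PathFileType\t4\t(X/Y/Z)\t{path}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\t"
        "OrigDataStartFrame\tOrigNumFrames",
        f"{t.rate:g}\t{t.rate:g}\t{n_frames}\t{n_markers}\t{units}\t"
        f"{t.rate:g}\t1\t{n_frames}",
        "Frame#\tTime\t" + "\t\t\t".join(t.names) + "\t\t",
        "\t\t" + "\t".join(
            f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(n_markers)
        ),
    ]
    for r in range(n_frames):
        cells = [str(r + 1), format(t.times[r], ".9g")]
        for m in range(n_markers):
            if t.mask[r, m]:
                cells.extend(
                    format(v * scale, ".9f") for v in t.positions[r, m]
                )
            else:
                cells.extend(["", "", ""])
        lines.append("\t".join(cells))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# MOT / STO


@dataclass(frozen=True)
class MotDocument:
    """A MOT/STO time-series table."""

    name: str
    in_degrees: bool
    data: pd.DataFrame  # first column is time

    def __post_init__(self):
        cols = list(self.data.columns)
        if len(cols) != len(set(cols)):
            raise ParseError("duplicate column labels in MOT table")


def read_mot(path) -> MotDocument:
    """Read a MOT/STO file."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    name = "motion"
    in_degrees = False
    n_rows = n_cols = None
    i = 0
    for i, ln in enumerate(lines):
        s = ln.strip()
        if s.lower() == "endheader":
            break
        if "=" in s:
            key, _, val = s.partition("=")
            key = key.strip().lower()
            val = val.strip()
            if key == "indegrees":
                in_degrees = val.lower() == "yes"
            elif key == "nrows":
                n_rows = int(val)
            elif key == "ncolumns":
                n_cols = int(val)
            elif key == "name":
                name = val
        elif s and i == 0:
            name = s
    else:
        raise ParseError("missing 'endheader' line")
    body = [ln for ln in lines[i + 1 :] if ln.strip()]
    if not body:
        raise ParseError("MOT file has no column-label row", line=i + 2)
    labels = body[0].split("\t")
    rows = []
    for r, ln in enumerate(body[1:]):
        cells = ln.split("\t")
        if len(cells) != len(labels):
            raise ParseError(
                f"row has {len(cells)} columns, expected {len(labels)}",
                line=i + 3 + r,
            )
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            raise ParseError(str(exc), line=i + 3 + r) from None
    if n_rows is not None and len(rows) != n_rows:
        raise ParseError(f"found {len(rows)} rows, header declares {n_rows}")
    if n_cols is not None and len(labels) != n_cols:
        raise ParseError(
            f"found {len(labels)} columns, header declares {n_cols}"
        )
    df = pd.DataFrame(rows, columns=labels)
    return MotDocument(name=name, in_degrees=in_degrees, data=df)


def write_mot(doc: MotDocument, path) -> None:
    df = doc.data
    with open(path, "w") as fh:
        fh.write(f"{doc.name}\n")
        fh.write("version=1\n")
        fh.write(f"nRows={len(df)}\n")
        fh.write(f"nColumns={len(df.columns)}\n")
        fh.write(f"inDegrees={'yes' if doc.in_degrees else 'no'}\n")
        fh.write("endheader\n")
        fh.write("\t".join(map(str, df.columns)) + "\n")
        for _, row in df.iterrows():
            fh.write("\t".join(format(v, ".10g") for v in row.to_numpy()) + "\n")


def coordinates_to_mot(times, names: Sequence[str], values, rotational_mask,
                       *, name: str = "coordinates",
                       in_degrees: bool = True) -> MotDocument:
    """Pack a coordinate trajectory (radians internally) into a MOT table,
    converting rotational columns to degrees when ``in_degrees``."""
    values = np.asarray(values, dtype=float).copy()
    rotational_mask = np.asarray(rotational_mask, dtype=bool)
    if in_degrees:
        values[:, rotational_mask] = np.rad2deg(values[:, rotational_mask])
    df = pd.DataFrame(values, columns=list(names))
    df.insert(0, "time", np.asarray(times, dtype=float))
    return MotDocument(name=name, in_degrees=in_degrees, data=df)


def mot_to_coordinates(doc: MotDocument, names: Sequence[str],
                       rotational_mask) -> tuple[np.ndarray, np.ndarray]:
    """Unpack a coordinate MOT table back to (times, radians)."""
    times = doc.data.iloc[:, 0].to_numpy(dtype=float)
    values = doc.data[list(names)].to_numpy(dtype=float).copy()
    if doc.in_degrees:
        rotational_mask = np.asarray(rotational_mask, dtype=bool)
        values[:, rotational_mask] = np.deg2rad(values[:, rotational_mask])
    return times, values


def loads_to_mot(loads: ExternalLoads,
                 prefixes: Mapping[str, str] | None = None,
                 *, name: str = "external_loads") -> MotDocument:
    """Pack external loads into a MOT table using the documented GRF
    column convention (prefix -> segment mapping, default
    :data:`DEFAULT_GRF_PREFIXES`)."""
    if prefixes is None:
        prefixes = DEFAULT_GRF_PREFIXES
    seg_to_prefix = {seg: p for p, seg in prefixes.items()}
    df = pd.DataFrame({"time": loads.times})
    for ch in loads.channels:
        p = seg_to_prefix.get(ch.segment, ch.segment)
        for j, ax in enumerate(_AXES):
            df[f"{p}_force_v{ax}"] = ch.force[:, j]
        for j, ax in enumerate(_AXES):
            df[f"{p}_force_p{ax}"] = ch.point[:, j]
        for j, ax in enumerate(_AXES):
            df[f"{p}_torque_{ax}"] = ch.moment[:, j]
    return MotDocument(name=name, in_degrees=False, data=df)


def loads_from_mot(doc: MotDocument,
                   prefixes: Mapping[str, str] | None = None) -> ExternalLoads:
    """Parse external loads out of a MOT table by the documented GRF
    column convention."""
    if prefixes is None:
        prefixes = DEFAULT_GRF_PREFIXES
    df = doc.data
    times = df.iloc[:, 0].to_numpy(dtype=float)
    channels = []
    for prefix, segment in prefixes.items():
        fcols = [f"{prefix}_force_v{ax}" for ax in _AXES]
        if not all(c in df.columns for c in fcols):
            continue
        force = df[fcols].to_numpy(dtype=float)
        point = df[[f"{prefix}_force_p{ax}" for ax in _AXES]].to_numpy(dtype=float)
        mcols = [f"{prefix}_torque_{ax}" for ax in _AXES]
        moment = (
            df[mcols].to_numpy(dtype=float)
            if all(c in df.columns for c in mcols)
            else np.zeros_like(force)
        )
        channels.append(LoadChannel(segment, force, point, moment))
    if not channels:
        raise ParseError(
            f"no GRF columns matching prefixes {list(prefixes)} in MOT table"
        )
    return ExternalLoads(times=times, channels=tuple(channels))
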