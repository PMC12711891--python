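"""OpenSim ``.mot`` motion-file IO and frame selection.

The ``.mot`` dialect accepted here: a free-form header of ``key=value`` lines
(case-insensitive keys; tab- or space-delimited; an optional bare first line is
treated as the trial name) terminated by ``endheader``, followed by one row of
column names (the first must be ``time``) and whitespace-delimited data rows.
The header's ``inDegrees`` flag (default ``yes``, the OpenSim convention)
controls whether rotational columns are converted to radians on read.

Which columns are rotational is decided by the bound skeletal model when one is
given, else by an overridable heuristic: every column except ``time`` is
rotational unless its name carries a translation marker (suffix ``_t``,
``_tx``, ``_ty`` or ``_tz``).
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import FormatError
from .skeletal_model import Pose, SkeletalModel

_TRANSLATION_SUFFIX = re.compile(r"_t[xyz]?$")


@dataclass
class MotionTrial:
    """One motion trial: time vector plus a frames x columns value matrix.

    Values are stored in internal units (radians / meters) after unit
    resolution at read time.
    """

    name: str
    column_names: List[str]
    times: np.ndarray
    values: np.ndarray
    source: str = "real"  # "real" | "random"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.times), len(self.column_names)):
            raise FormatError(
                f"trial {self.name!r}: value matrix shape {self.values.shape} does not match "
                f"{len(self.times)} frames x {len(self.column_names)} columns")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise FormatError(f"trial {self.name!r}: times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)


def _rotational_mask(columns: Sequence[str], model: Optional[SkeletalModel],
                     rotation_columns: Optional[Sequence[str]]) -> np.ndarray:
    if rotation_columns is not None:
        rot = set(rotation_columns)
        return np.array([c in rot for c in columns])
    if model is not None:
        rot = set(model.rotational_coordinates())
        return np.array([c in rot for c in columns])
    return np.array([_TRANSLATION_SUFFIX.search(c) is None for c in columns])


def read_mot(path, model: Optional[SkeletalModel] = None,
             rotation_columns: Optional[Sequence[str]] = None,
             source: str = "real") -> MotionTrial:
    """Read a ``.mot`` file, converting degree columns to radians if needed."""
    path = Path(path)
    lines = path.read_text().splitlines()
    header = {}
    name = path.stem
    end = None
    for i, line in enumerate(lines):
        stripped = line.strip()
        if stripped.lower() == "endheader":
            end = i
            break
        if "=" in stripped:
            key, _, val = stripped.partition("=")
            header[key.strip().lower()] = val.strip()
        elif stripped and i == 0:
            name = stripped
    if end is None:
        raise FormatError(f"{path.name}: no 'endheader' line found")

    body = [(i + 1, ln) for i, ln in enumerate(lines) if i > end and ln.strip()]
    if not body:
        raise FormatError(f"{path.name}: no column-header row after endheader")
    col_line_no, col_line = body[0]
    columns = col_line.split()
    if not columns or columns[0].lower() != "time":
        raise FormatError(f"{path.name}, line {col_line_no}: first column must be 'time'")
    data_cols = columns[1:]

    times, rows = [], []
    for line_no, ln in body[1:]:
        parts = ln.split()
        if len(parts) != len(columns):
            raise FormatError(
                f"{path.name}, line {line_no}: expected {len(columns)} values, got {len(parts)}")
        try:
            vals = [float(p) for p in parts]
        except ValueError as exc:
            raise FormatError(f"{path.name}, line {line_no}: non-numeric value ({exc})") from exc
        times.append(vals[0])
        rows.append(vals[1:])

    values = np.asarray(rows, dtype=float).reshape(len(times), len(data_cols))
    in_degrees = header.get("indegrees", "yes").strip().lower() in ("yes", "true", "1")
    if in_degrees and values.size:
        rot = _rotational_mask(data_cols, model, rotation_columns)
        values[:, rot] = np.deg2rad(values[:, rot])
    return MotionTrial(name=header.get("name", name), column_names=data_cols,
                       times=np.asarray(times), values=values, source=source)


def write_mot(trial: MotionTrial, path) -> None:
    """Write a trial as a ``.mot`` file (always ``inDegrees=no``, i.e. radians)."""
    if trial.n_frames == 0:
        raise FormatError(f"trial {trial.name!r} has no frames; refusing to write empty .mot")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{trial.name}\n")
        fh.write(f"nRows={trial.n_frames}\n")
        fh.write(f"nColumns={len(trial.column_names) + 1}\n")
        fh.write("inDegrees=no\n")
        fh.write("endheader\n")
        fh.write("\t".join(["time"] + list(trial.column_names)) + "\n")
        for t, row in zip(trial.times, trial.values):
            fh.write("\t".join(f"{v:.17g}" for v in [t, *row]) + "\n")


def extract_equal_frames(trials: Sequence[MotionTrial], total: int) -> List[Tuple[str, int]]:
    """Select `total` frames spread equally across trials.

    Per-trial quota is ``floor(total / n_trials)``; the remainder goes to the
    first ``total mod n_trials`` trials in input order.  Within a trial the
    selected indices are evenly strided from the first to the last frame.
    """
    if not trials:
        raise ValueError("no trials given")
    if total < len(trials):
        raise ValueError(f"total={total} is less than the number of trials ({len(trials)})")
    n = len(trials)
    base, rem = divmod(total, n)
    out: List[Tuple[str, int]] = []
    for i, trial in enumerate(trials):
        quota = base + (1 if i < rem else 0)
        if trial.n_frames == 0:
            raise ValueError(f"trial {trial.name!r} is empty")
        if quota > trial.n_frames:
            raise ValueError(
                f"trial {trial.name!r}: quota {quota} exceeds its {trial.n_frames} frames")
        if quota == 1:
            idx = [0]
        else:
            idx = [int(round(k * (trial.n_frames - 1) / (quota - 1))) for k in range(quota)]
        out.extend((trial.name, j) for j in idx)
    return out


def pose_from_frame(model: SkeletalModel, trial: MotionTrial, index: int) -> Pose:
    """Build a pose from one trial frame, matching columns to coordinates by name.

    Coordinates absent from the trial take their model default; extra columns
    are ignored with a warning.
    """
    if not 0 <= index < trial.n_frames:
        raise IndexError(f"frame index {index} out of range for trial {trial.name!r}")
    row = dict(zip(trial.column_names, trial.values[index]))
    extra = [c for c in trial.column_names if c not in set(model.coordinate_names)]
    if extra:
        warnings.warn(f"trial {trial.name!r}: ignoring columns not in model: {extra}",
                      stacklevel=2)
    return {c.name: float(row.get(c.name, c.default)) for c in model.coordinates}
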