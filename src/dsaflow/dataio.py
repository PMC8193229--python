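"""Readers and writers for DSA frame stacks, detection tables and feature tables.

Conventions used throughout the package:

* frame indices are 0-based;
* bounding boxes are 0-based, half-open pixel rectangles
  ``[x_min, x_max) x [y_min, y_max)``, so box area is simply
  ``(x_max - x_min) * (y_max - y_min)``;
* detection tables are RFC-4180 CSV with the fixed header
  ``case_id,frame,label,x_min,y_min,x_max,y_max,score`` where an empty
  ``score`` marks a ground-truth annotation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

#: the five vascular structure classes, in canonical order of hemodynamic
#: appearance in a normal run (arterial -> venous)
STRUCTURE_CLASSES = (
    "carotid_artery",
    "willis_circle",
    "vein",
    "venous_vessel",
    "venous_sinus",
)

DETECTION_COLUMNS = (
    "case_id",
    "frame",
    "label",
    "x_min",
    "y_min",
    "x_max",
    "y_max",
    "score",
)


class FormatError(ValueError):
    """Raised when an on-disk artifact violates the documented format."""


@dataclass
class FrameStack:
    """Ordered grayscale frames of one DSA acquisition run.

    Parameters
    ----------
    case_id:
        Identifier of the acquisition (usually the case directory name).
    frames:
        3D array ``(n_frames, height, width)``; 8- or 16-bit unsigned
        integer or float.
    frame_interval_ms:
        Time between consecutive frames in milliseconds.  Clinical
        acquisitions run at 166-333 ms/frame.
    """

    case_id: str
    frames: np.ndarray
    frame_interval_ms: float = 250.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise FormatError(
                f"frames must be a (n_frames, h, w) array with >= 1 frame, "
                f"got shape {self.frames.shape}"
            )

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return (int(self.frames.shape[1]), int(self.frames.shape[2]))

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]


_NUM_RE = re.compile(r"(\d+)")


def _numeric_key(name: str) -> tuple:
    """Sort key: split a filename into (text, number, text, ...) chunks.

    ``frame_2.png`` sorts before ``frame_10.png`` (numeric, not
    lexicographic, comparison of the digit runs).
    """
    parts = _NUM_RE.split(name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def read_frame_stack(path: str | Path, frame_interval_ms: float = 250.0) -> FrameStack:
    """Read a DSA frame stack from disk.

    ``path`` may be a directory of numbered PNG/TIFF frames, a multipage
    TIFF file, or a multi-frame DICOM object.  Directory frames are ordered
    by numeric filename index (digit runs compared as integers).  For DICOM,
    the object's frame time (0018,1063), when present, overrides the
    ``frame_interval_ms`` argument.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir()
             if p.suffix.lower() in {".png", ".tif", ".tiff"}),
            key=lambda p: _numeric_key(p.name),
        )
        if not files:
            raise FormatError(f"no PNG/TIFF frames found in directory {path}")
        frames = [np.asarray(iio.imread(f)) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise FormatError(
                f"mixed frame dimensions in {path}: {sorted(shapes)}"
            )
        if frames[0].ndim != 2:
            raise FormatError("frames must be single-channel grayscale images")
        return FrameStack(path.name, np.stack(frames), frame_interval_ms)

    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise FormatError(f"expected a multipage grayscale TIFF, got shape {arr.shape}")
        return FrameStack(path.stem, arr, frame_interval_ms)

    if path.suffix.lower() in {".dcm", ".dicom"} or path.is_file():
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array
        if arr.ndim == 2:
            arr = arr[None]
        interval = frame_interval_ms
        ft = ds.get("FrameTime", None)
        if ft is not None:
            interval = float(ft)
        return FrameStack(path.stem, np.asarray(arr), interval)

    raise FormatError(f"cannot read frame stack from {path}")  # pragma: no cover


def _validate_detection_frame(df: pd.DataFrame, where: str) -> pd.DataFrame:
    missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{where}: missing columns {missing}")
    df = df.loc[:, list(DETECTION_COLUMNS)].copy()
    bad = ~df["label"].isin(STRUCTURE_CLASSES)
    if bad.any():
        row = df.index[bad][0]
        raise FormatError(
            f"{where}: unknown label {df.loc[row, 'label']!r} in row {row} "
            f"(allowed: {', '.join(STRUCTURE_CLASSES)})"
        )
    for c in ("frame", "x_min", "y_min", "x_max", "y_max"):
        df[c] = df[c].astype(int)
    df["score"] = pd.to_numeric(df["score"], errors="coerce")
    degen = (df["x_min"] >= df["x_max"]) | (df["y_min"] >= df["y_max"])
    if degen.any():
        row = df.index[degen][0]
        raise FormatError(
            f"{where}: degenerate box in row {row} "
            f"(need x_min < x_max and y_min < y_max, half-open)"
        )
    return df.reset_index(drop=True)


def new_detection_table(rows: Sequence[tuple] = ()) -> pd.DataFrame:
    """Build a detection table DataFrame from row tuples in column order."""
    df = pd.DataFrame(list(rows), columns=list(DETECTION_COLUMNS))
    if len(df) == 0:
        df = df.astype(
            {"frame": int, "x_min": int, "y_min": int, "x_max": int,
             "y_max": int, "score": float, "case_id": object, "label": object}
        )
        return df
    return _validate_detection_frame(df, "new_detection_table")


def write_detection_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a detection/annotation table as CSV.

    Ground-truth rows (score = NaN) are written with an empty score field.
    The writer is deterministic: identical tables give byte-identical files.
    """
    df = _validate_detection_frame(pd.DataFrame(rows), "write_detection_table")
    # default float repr is shortest-round-trip, so write -> read is identity
    df.to_csv(path, index=False, lineterminator="\n")


def read_detection_table(path: str | Path) -> pd.DataFrame:
    """Read a detection table CSV; empty scores come back as NaN ("no score")."""
    df = pd.read_csv(path, dtype={"case_id": str, "label": str})
    return _validate_detection_frame(df, str(path))


def write_feature_table(
    case_ids: Sequence[str],
    diagnoses: Sequence[str],
    grade_classes: Sequence[str],
    features: pd.DataFrame,
    path: str | Path,
) -> pd.DataFrame:
    """Write the per-case feature table.

    Columns: ``case_id, diagnosis, grade_class`` then the feature columns in
    their canonical order (temporal T1..T5 first, then radiomics
    frame-major), exactly as given in ``features``.  All cases must share
    one feature-name set; the writer is deterministic.
    """
    if features.isna().any().any():
        raise ValueError("feature table contains missing values (ragged feature sets?)")
    n = len(features)
    if not (len(case_ids) == len(diagnoses) == len(grade_classes) == n):
        raise ValueError("case_ids, diagnoses, grade_classes and features disagree in length")
    out = pd.concat(
        [
            pd.DataFrame(
                {"case_id": list(case_ids), "diagnosis": list(diagnoses),
                 "grade_class": list(grade_classes)}
            ),
            features.reset_index(drop=True),
        ],
        axis=1,
    )
    out.to_csv(path, index=False, lineterminator="\n")
    return out


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"case_id": str, "diagnosis": str, "grade_class": str})
    for c in ("case_id", "diagnosis", "grade_class"):
        if c not in df.columns:
            raise FormatError(f"{path}: missing metadata column {c!r}")
    return df


def load_config(path: str | Path) -> dict:
    """Load a YAML pipeline-parameter file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return cfg
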