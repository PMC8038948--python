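"""Reading and writing localization tables and downstream tabular artifacts.

Single-molecule localization microscopy (SMLM) software exports one row per
detected blink event ("localization"): a channel label, x/y coordinates,
the camera frame index, and usually a localization-accuracy estimate.
Internally everything is carried as a :class:`pandas.DataFrame` with the
canonical columns ``channel, x, y, frame, accuracy, id`` — coordinates in
nanometres, frames 1-based, ids assigned in file order.

Table-level metadata (total frame count, provenance) rides on
``DataFrame.attrs``.
"""

from __future__ import annotations

import io as _io
import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "TableDialect",
    "NSTORM_DIALECT",
    "read_localizations",
    "filter_frames",
    "write_table",
    "read_table",
    "empty_localization_table",
]

#: canonical internal columns of a localization table
LOC_COLUMNS = ["channel", "x", "y", "frame", "accuracy", "id"]


@dataclass(frozen=True)
class TableDialect:
    """Column-name mapping and unit convention for a localization export.

    Export column names vary between acquisition-software versions, so the
    mapping is configurable.  ``unit`` is either ``"nm"`` or ``"px"``; pixel
    coordinates are converted to nm at read time using ``pixel_size_nm``.
    The accuracy column is optional: if the named column is absent from the
    file the field is carried as missing rather than fabricated.
    """

    channel: str = "Channel Name"
    x: str = "X [nm]"
    y: str = "Y [nm]"
    frame: str = "Frame"
    accuracy: str | None = "Accuracy [nm]"
    delimiter: str = "\t"
    unit: str = "nm"
    pixel_size_nm: float = 160.0

    def __post_init__(self) -> None:
        if self.unit not in ("nm", "px"):
            raise ValueError(f"unit must be 'nm' or 'px', got {self.unit!r}")
        if self.unit == "px" and not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be positive for pixel input")


#: default dialect matching NSTORM-style tab-delimited exports
NSTORM_DIALECT = TableDialect()


def empty_localization_table(n_frames_total: int = 0, source: str = "") -> pd.DataFrame:
    t = pd.DataFrame(
        {
            "channel": pd.Series(dtype=str),
            "x": pd.Series(dtype=float),
            "y": pd.Series(dtype=float),
            "frame": pd.Series(dtype=np.int64),
            "accuracy": pd.Series(dtype=float),
            "id": pd.Series(dtype=np.int64),
        }
    )
    t.attrs["n_frames_total"] = int(n_frames_total)
    t.attrs["source"] = source
    return t


def _numeric(raw: pd.Series, colname: str, path: str | os.PathLike) -> pd.Series:
    """Coerce a column to float, reporting the file line of the first bad cell."""
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna()
    if bad.any():
        # +2: one for the header line, one for 0- vs 1-based indexing
        line = int(bad.idxmax()) + 2
        raise ValueError(
            f"{path}: non-numeric value {raw[bad.idxmax()]!r} in column "
            f"{colname!r} at line {line}"
        )
    return out.astype(float)


def read_localizations(
    path: str | os.PathLike,
    dialect: TableDialect = NSTORM_DIALECT,
    n_frames_total: int | None = None,
) -> pd.DataFrame:
    """Read a delimited localization list into the canonical table.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    dialect
        Column mapping / units; see :class:`TableDialect`.
    n_frames_total
        Length of the acquisition stack.  Defaults to the maximum frame
        present in the file (localization lists do not always record it).

    Returns
    -------
    pandas.DataFrame
        Columns ``channel, x, y, frame, accuracy, id``; ids are assigned in
        file order starting at 1; positions are in nm.
    """
    raw = pd.read_csv(path, sep=dialect.delimiter, dtype=str)
    required = {
        "channel": dialect.channel,
        "x": dialect.x,
        "y": dialect.y,
        "frame": dialect.frame,
    }
    for field, col in required.items():
        if col not in raw.columns:
            raise ValueError(f"{path}: missing required column {col!r} (maps to {field})")

    scale = dialect.pixel_size_nm if dialect.unit == "px" else 1.0
    x = _numeric(raw[dialect.x], dialect.x, path) * scale
    y = _numeric(raw[dialect.y], dialect.y, path) * scale
    frame_f = _numeric(raw[dialect.frame], dialect.frame, path)
    frame = frame_f.astype(np.int64)
    if len(frame) and (frame < 1).any():
        raise ValueError(f"{path}: frame indices must be >= 1 (1-based)")

    if dialect.accuracy is not None and dialect.accuracy in raw.columns:
        accuracy = _numeric(raw[dialect.accuracy], dialect.accuracy, path)
        if dialect.unit == "px":
            accuracy = accuracy * scale
    else:
        accuracy = pd.Series(np.nan, index=raw.index, dtype=float)

    t = pd.DataFrame(
        {
            "channel": raw[dialect.channel].astype(str),
            "x": x,
            "y": y,
            "frame": frame,
            "accuracy": accuracy,
            "id": np.arange(1, len(raw) + 1, dtype=np.int64),
        }
    )
    if not np.isfinite(t[["x", "y"]].to_numpy()).all():
        raise ValueError(f"{path}: non-finite coordinate encountered")
    max_frame = int(t["frame"].max()) if len(t) else 0
    if n_frames_total is None:
        n_frames_total = max_frame
    elif n_frames_total < max_frame:
        raise ValueError(
            f"n_frames_total={n_frames_total} is smaller than the largest frame "
            f"present ({max_frame})"
        )
    t.attrs["n_frames_total"] = int(n_frames_total)
    t.attrs["source"] = str(path)
    return t


def filter_frames(
    t: pd.DataFrame, first_excluded: int = 100, last_excluded: int = 10
) -> pd.DataFrame:
    """Drop localizations from the start and end of the acquisition.

    Early frames are recorded while fluorophores are still being driven into
    the dark state and the tail frames carry optical-reconfiguration
    artifacts, so both are excluded before analysis.  Keeps exactly the rows
    with ``first_excluded < frame <= n_frames_total - last_excluded``.
    Idempotent, and preserves ids.
    """
    n_total = int(t.attrs.get("n_frames_total") or (t["frame"].max() if len(t) else 0))
    if len(t) == 0:
        out = t.copy()
        out.attrs = dict(t.attrs)
        return out
    if n_total <= first_excluded + last_excluded:
        raise ValueError(
            f"no frames remain: n_frames_total={n_total} <= "
            f"{first_excluded} + {last_excluded}"
        )
    keep = (t["frame"] > first_excluded) & (t["frame"] <= n_total - last_excluded)
    out = t.loc[keep].reset_index(drop=True)
    out.attrs = dict(t.attrs)
    out.attrs["n_frames_total"] = n_total
    return out


def write_table(rows: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write any tabular result as CSV with header.

    Floats are written with 17 significant digits, so a read-back through
    :func:`read_table` reproduces values bit-exactly.
    """
    rows.to_csv(path, index=False, float_format="%.17g")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_table`."""
    return pd.read_csv(path, float_precision="round_trip")
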