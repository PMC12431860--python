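"""Readers and writers for image stacks, localization tables and traces.

Conventions used throughout the package:

* images are ``(t, y, x)`` arrays, 0-based, pixel-centre coordinates,
  y increasing downward;
* localization tables carry coordinates in nanometres;
* pixel calibrations attach physical units to image data.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("aggrequant")

SPACE_UNITS = ("um", "nm")
TIME_UNITS = ("h", "min", "s")

#: accepted aliases for localization-table columns, all case-insensitive
_LOC_ALIASES = {
    "x_nm": ("x_nm", "x [nm]", "x(nm)", "x"),
    "y_nm": ("y_nm", "y [nm]", "y(nm)", "y"),
    "frame": ("frame", "frame_idx", "t"),
    "sigma_nm": ("sigma_nm", "uncertainty_nm", "uncertainty [nm]",
                 "loc_error_nm", "sigma"),
    "photons": ("photons", "intensity [photon]", "n_photons"),
}


@dataclass(frozen=True)
class PixelCalibration:
    """Physical calibration of an image stack.

    Parameters
    ----------
    pixel_size : float
        Physical length per pixel (strictly positive), in ``space_unit``.
    frame_interval : float
        Time between consecutive frames (strictly positive), in
        ``time_unit``.
    space_unit : {"um", "nm"}
    time_unit : {"h", "min", "s"}
    """

    pixel_size: float
    frame_interval: float
    space_unit: str = "um"
    time_unit: str = "h"

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be strictly positive")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be strictly positive")
        if self.space_unit not in SPACE_UNITS:
            raise ValueError(f"space_unit must be one of {SPACE_UNITS}")
        if self.time_unit not in TIME_UNITS:
            raise ValueError(f"time_unit must be one of {TIME_UNITS}")

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size * (1e-3 if self.space_unit == "nm" else 1.0)

    @property
    def pixel_size_nm(self) -> float:
        return self.pixel_size * (1e3 if self.space_unit == "um" else 1.0)


@dataclass
class FrameStack:
    """A time-ordered stack of 2-D images for one channel."""

    data: np.ndarray  # (t, y, x)
    calibration: PixelCalibration
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError("FrameStack data must be (t, y, x)")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_times(self) -> np.ndarray:
        """Frame acquisition times in the calibration's time unit."""
        return np.arange(self.n_frames) * self.calibration.frame_interval

    def __len__(self) -> int:
        return self.n_frames


def read_stack(path, calibration: PixelCalibration) -> list[FrameStack]:
    """Read a TIFF file into one :class:`FrameStack` per channel.

    Accepts 2-D single frames, 3-D ``(t, y, x)`` stacks and 4-D
    ``(t, c, y, x)`` stacks.  Pixel values are preserved bit-exactly.

    Raises
    ------
    ValueError
        If the file cannot be read, the dimensionality is unsupported,
        or a 3-D stack's axis order is ambiguous (small leading axis
        that could equally be channels) — the error names the layout
        that would have been assumed.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            axes = tf.series[0].axes if tf.series else ""
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise ValueError(f"unreadable TIFF file {path}: {exc}") from exc

    if arr.ndim == 2:
        arr = arr[None]
        axes = "TYX"  # a single frame is unambiguous
    # tifffile reports unknown axes as 'Q' (or 'I' for plain series)
    known = set(axes) <= set("TCZYX") and len(axes) == arr.ndim
    if arr.ndim == 3:
        if known and "C" in axes and "T" not in axes:
            # channel stack without time: one single-frame stack per channel
            c_ax = axes.index("C")
            arr = np.moveaxis(arr, c_ax, 0)
            return [FrameStack(a[None].copy(), calibration, channel=f"ch{i}")
                    for i, a in enumerate(arr)]
        if not known and arr.shape[0] <= 4 and \
                arr.shape[0] < min(arr.shape[1:]):
            raise ValueError(
                f"ambiguous 3-D stack in {path}: leading axis of length "
                f"{arr.shape[0]} could be time or channels; the assumed "
                "layout would be (t, y, x) — re-save with axis metadata or "
                "split channels explicitly"
            )
        return [FrameStack(arr.copy(), calibration)]
    if arr.ndim == 4:
        if known and axes not in ("TCYX", "CTYX"):
            raise ValueError(
                f"unsupported 4-D axis order {axes!r} in {path}; expected "
                "(t, c, y, x)"
            )
        if axes == "CTYX":
            arr = np.swapaxes(arr, 0, 1)
        return [FrameStack(arr[:, c].copy(), calibration, channel=f"ch{c}")
                for c in range(arr.shape[1])]
    raise ValueError(f"unsupported TIFF dimensionality {arr.ndim} in {path}")


def write_stack(stack: FrameStack | np.ndarray, path) -> None:
    """Write a stack to TIFF with (t, y, x) axis order."""
    data = stack.data if isinstance(stack, FrameStack) else np.asarray(stack)
    tifffile.imwrite(path, data, metadata={"axes": "TYX"})


def _find_column(columns: Sequence[str], canonical: str) -> str | None:
    lowered = {c.lower().strip(): c for c in columns}
    for alias in _LOC_ALIASES[canonical]:
        if alias in lowered:
            return lowered[alias]
    return None


def read_localizations(path) -> pd.DataFrame:
    """Read an SMLM localization table from CSV.

    Required columns (aliases accepted, case-insensitive): x, y in nm and
    frame.  Optional: localization uncertainty (``sigma_nm``) and photon
    count.  Rows with non-finite coordinates are dropped and the count is
    logged.
    """
    df = pd.read_csv(path)
    out = pd.DataFrame()
    for canonical, required in (("x_nm", True), ("y_nm", True),
                                ("frame", True), ("sigma_nm", False),
                                ("photons", False)):
        col = _find_column(df.columns, canonical)
        if col is None:
            if required:
                raise ValueError(
                    f"localization table {path} is missing required column "
                    f"{canonical!r} (accepted aliases: "
                    f"{_LOC_ALIASES[canonical]})"
                )
            continue
        out[canonical] = pd.to_numeric(df[col], errors="coerce")
    finite = np.isfinite(out["x_nm"]) & np.isfinite(out["y_nm"])
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.warning("read_localizations: dropped %d/%d rows with "
                       "non-finite coordinates", n_dropped, len(out))
    out = out.loc[finite].reset_index(drop=True)
    out["frame"] = out["frame"].astype(int)
    return out


def write_localizations(table: pd.DataFrame, path) -> None:
    """Write a localization table to CSV with nm units in the header."""
    cols = [c for c in ("x_nm", "y_nm", "frame", "sigma_nm", "photons")
            if c in table.columns]
    table.loc[:, cols].to_csv(path, index=False)


def write_table(records, path) -> None:
    """Write any tabular result (DataFrame, TimeSeries, PunctaSet,
    ClusterResult summary) to CSV with a stable column order."""
    frame = _as_frame(records)
    frame.to_csv(path, index=False)


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    if hasattr(records, "to_frame"):
        return records.to_frame()
    if isinstance(records, (list, tuple)) and records and \
            hasattr(records[0], "to_frame"):
        return pd.concat([r.to_frame() for r in records], ignore_index=True)
    raise TypeError(f"cannot serialise {type(records).__name__} as a table")
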