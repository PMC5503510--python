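"""Localization-table I/O, detection-threshold filtering, rasterization.

Single-molecule localization microscopy produces an event list: each
detected fluorophore switching cycle yields an (x, y) position in nm, the
acquisition frame, a photon count and a wavelength-channel label.  This
module reads and writes those tables, applies the photon detection floor,
bins events onto a fixed-pixel grid (the substrate for all cluster
analysis) and quantifies spectral bleed-through between channels.

Coordinate conventions
----------------------
Positions are continuous nm with the origin at the field corner.  Pixels
are half-open intervals ``[k*p, (k+1)*p)`` of width ``p`` nm; grids are
indexed row-major as ``(y, x)`` i.e. ``grid[row, col]`` with
``row = floor((y - y0)/p)`` and ``col = floor((x - x0)/p)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: canonical column order of the in-memory table
COLUMNS = ["x_nm", "y_nm", "frame", "photons", "channel"]

#: column-name mappings for known delimited-text dialects
DIALECTS = {
    "simple": {
        "x_nm": "x_nm",
        "y_nm": "y_nm",
        "frame": "frame",
        "photons": "photons",
        "channel": "channel",
    },
    # ThunderSTORM CSV export; it carries no channel column, so the channel
    # label is supplied by the caller.
    "thunderstorm": {
        "x_nm": "x [nm]",
        "y_nm": "y [nm]",
        "frame": "frame",
        "photons": "intensity [photon]",
        "channel": None,
    },
}


class LocalizationError(ValueError):
    """Raised for malformed localization tables."""


@dataclass
class LocalizationTable:
    """Per-event table for one acquisition channel.

    ``df`` holds at least the columns in :data:`COLUMNS`; extra columns
    (e.g. an ``above_threshold`` flag from the simulator) are carried
    through untouched.
    """

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise LocalizationError(f"missing mandatory column(s): {missing}")
        self.validate()

    def validate(self) -> None:
        """Check row invariants; errors name the offending row."""
        x = self.df["x_nm"].to_numpy(float)
        y = self.df["y_nm"].to_numpy(float)
        bad = np.flatnonzero(~(np.isfinite(x) & np.isfinite(y)))
        if bad.size:
            raise LocalizationError(f"non-finite coordinate at row {bad[0]}")
        p = self.df["photons"].to_numpy(float)
        bad = np.flatnonzero(~(np.isfinite(p) & (p > 0)))
        if bad.size:
            raise LocalizationError(
                f"photons must be > 0; violated at row {bad[0]} "
                f"(photons={p[bad[0]]})"
            )
        ch = self.df["channel"].astype(str)
        bad = np.flatnonzero(ch.str.len().to_numpy() == 0)
        if bad.size:
            raise LocalizationError(f"empty channel label at row {bad[0]}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def x_nm(self) -> np.ndarray:
        return self.df["x_nm"].to_numpy(float)

    @property
    def y_nm(self) -> np.ndarray:
        return self.df["y_nm"].to_numpy(float)

    @property
    def photons(self) -> np.ndarray:
        return self.df["photons"].to_numpy(float)


@dataclass
class RasterMap:
    """2D pixel grid at a fixed nm pixel size.

    ``grid`` holds event counts (int) or binary occupancy (bool);
    ``footprint`` optionally restricts the analyzable area (e.g. the cell
    outline) and must have the same shape as ``grid``.
    """

    grid: np.ndarray
    pixel_size_nm: float = 20.0
    origin_nm: tuple[float, float] = (0.0, 0.0)
    footprint: np.ndarray | None = None

    def __post_init__(self):
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.footprint is not None and self.footprint.shape != self.grid.shape:
            raise ValueError("footprint shape must match grid shape")

    @property
    def binary(self) -> np.ndarray:
        """Boolean occupancy view of the grid."""
        return self.grid.astype(bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def save_tiff(self, path) -> None:
        """Export as 16-bit TIFF (counts clipped to uint16 range)."""
        import tifffile

        arr = np.clip(self.grid.astype(np.int64), 0, 2**16 - 1).astype(np.uint16)
        tifffile.imwrite(str(path), arr)

    def save_text(self, path) -> None:
        np.savetxt(path, self.grid.astype(int), fmt="%d", delimiter="\t")


def read_localizations(
    path,
    dialect: str = "auto",
    channel: str | None = None,
    sep: str = ",",
) -> LocalizationTable:
    """Read a delimited-text localization table.

    Parameters
    ----------
    dialect:
        ``"simple"`` (this package's own header), ``"thunderstorm"`` or
        ``"auto"`` to sniff the header.
    channel:
        Channel label to assign when the dialect carries no channel column.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=sep)
    if dialect == "auto":
        for name, mapping in DIALECTS.items():
            needed = [v for v in mapping.values() if v is not None]
            if all(c in raw.columns for c in needed):
                dialect = name
                break
        else:
            raise LocalizationError(
                f"could not match columns {list(raw.columns)} to a known dialect"
            )
    mapping = DIALECTS[dialect]
    out = {}
    for key, col in mapping.items():
        if col is None:
            continue
        if col not in raw.columns:
            raise LocalizationError(f"missing mandatory column {col!r} in {path}")
        out[key] = raw[col]
    df = pd.DataFrame(out)
    if "frame" not in df.columns:
        df["frame"] = 0
    if "channel" not in df.columns:
        df["channel"] = channel if channel is not None else "unknown"
    df["channel"] = df["channel"].astype(str)
    for col in ("x_nm", "y_nm", "photons"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy())
        if bad.size:
            raise LocalizationError(
                f"non-numeric value in column {col!r} at row {bad[0]}"
            )
        df[col] = vals
    return LocalizationTable(df[COLUMNS], metadata={"source_file": str(path)})


def write_localizations(table: LocalizationTable, path) -> None:
    """Write with the 'simple' header (x_nm, y_nm, frame, photons, channel)."""
    table.df.to_csv(path, index=False, columns=COLUMNS)


def filter_by_photons(table: LocalizationTable, threshold: float = 50) -> LocalizationTable:
    """Discard events with photon counts below the detection floor.

    Events with ``photons < threshold`` are treated as noise and dropped;
    the boundary value is retained (an event with exactly ``threshold``
    photons passes).  The number of discarded events is logged.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    keep = table.df["photons"].to_numpy(float) >= threshold
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("filter_by_photons: discarded %d/%d events below %g photons",
                 n_drop, len(table), threshold)
    md = dict(table.metadata)
    md["n_discarded_below_threshold"] = md.get("n_discarded_below_threshold", 0) + n_drop
    return LocalizationTable(table.df.loc[keep].reset_index(drop=True), md)


def rasterize(
    table: LocalizationTable,
    pixel_size_nm: float = 20.0,
    binary: bool = False,
    origin_nm: tuple[float, float] = (0.0, 0.0),
    shape: tuple[int, int] | None = None,
    extent_nm: tuple[float, float] | None = None,
) -> RasterMap:
    """Bin events to a pixel grid.

    An event at ``(x, y)`` lands in pixel
    ``(floor((y - y0)/p), floor((x - x0)/p))``.  Total counts are
    conserved.  ``shape`` (rows, cols) or ``extent_nm`` (width, height)
    fixes the grid; otherwise the grid is sized to cover all events.
    Events outside a declared extent raise an error.
    """
    if len(table) == 0:
        raise LocalizationError("cannot rasterize an empty table")
    x0, y0 = origin_nm
    col = np.floor((table.x_nm - x0) / pixel_size_nm).astype(np.int64)
    row = np.floor((table.y_nm - y0) / pixel_size_nm).astype(np.int64)
    if shape is None and extent_nm is None:
        extent_nm = table.metadata.get("extent_nm")
    if shape is None:
        if extent_nm is not None:
            w, h = extent_nm
            shape = (int(np.ceil(h / pixel_size_nm)), int(np.ceil(w / pixel_size_nm)))
        else:
            if (row < 0).any() or (col < 0).any():
                raise LocalizationError("event outside declared extent (negative index)")
            shape = (int(row.max()) + 1, int(col.max()) + 1)
    bad = (row < 0) | (row >= shape[0]) | (col < 0) | (col >= shape[1])
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise LocalizationError(
            f"event at row {i} ({table.x_nm[i]:g}, {table.y_nm[i]:g}) nm "
            f"falls outside the declared extent"
        )
    grid = np.zeros(shape, dtype=np.int64)
    np.add.at(grid, (row, col), 1)
    if binary:
        grid = grid >= 1
    return RasterMap(grid, pixel_size_nm=pixel_size_nm, origin_nm=(x0, y0))


def bleedthrough_fraction(
    wrong_channel: LocalizationTable, correct_channel: LocalizationTable
) -> float:
    """Total events detected in the wrong channel over those in the correct one.

    This is the standard two-color cross-talk measure: image a structure
    labeled with a single fluorophore in both channels and take the event
    ratio.
    """
    if len(correct_channel) == 0:
        raise LocalizationError("bleed-through undefined: correct channel is empty")
    return len(wrong_channel) / len(correct_channel)


def convex_footprint(
    mask_or_table,
    pixel_size_nm: float = 20.0,
    dilate_nm: float = 100.0,
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Convex hull of the occupied pixels, dilated by ``dilate_nm``.

    Stands in for the cell outline when no explicit footprint is
    available.
    """
    from skimage.morphology import convex_hull_image, binary_dilation, disk

    if isinstance(mask_or_table, LocalizationTable):
        rmap = rasterize(mask_or_table, pixel_size_nm=pixel_size_nm,
                         binary=True, shape=shape)
        mask = rmap.binary
        pixel_size_nm = rmap.pixel_size_nm
    elif isinstance(mask_or_table, RasterMap):
        mask = mask_or_table.binary
        pixel_size_nm = mask_or_table.pixel_size_nm
    else:
        mask = np.asarray(mask_or_table, dtype=bool)
    hull = convex_hull_image(mask)
    r = max(1, int(round(dilate_nm / pixel_size_nm)))
    return binary_dilation(hull, disk(r))
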