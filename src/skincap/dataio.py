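"""Readers and writers for capacitive skin images and repeat-measurement tables.

Capacitive images are 8-bit single-channel grey maps produced by a
fingerprint-sensor die (brighter grey = higher permittivity = more surface
water).  Two on-disk forms are supported: single-channel 8-bit PNG and a
headerless comma-separated integer grid (row-major, top row first).
Measurement tables are CSV with columns
``site_id,timepoint,instrument,replicate,value``.

Every other module operates only on the in-memory types defined here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "CapacitiveImage",
    "MeasurementSeries",
    "DEFAULT_PIXEL_PITCH_UM",
    "read_image",
    "write_image",
    "read_measurements",
    "write_measurements",
]

#: Centre-to-centre pixel spacing of the sensing die, micrometres.  Metadata
#: only: no scoring or statistic in this package depends on it.
DEFAULT_PIXEL_PITCH_UM = 50.0

MEASUREMENT_COLUMNS = ("site_id", "timepoint", "instrument", "replicate", "value")


@dataclass(frozen=True)
class CapacitiveImage:
    """A single capacitive frame: an integer grey-level grid plus metadata.

    Parameters
    ----------
    pixels
        2-D integer array, ``height x width``, each value in
        ``[0, 2**bit_depth - 1]``.  Stored as ``uint8``.
    pixel_pitch
        Physical pixel spacing in micrometres (metadata only).
    bit_depth
        Grey-level resolution in bits; the supported sensors are 8-bit.
    """

    pixels: np.ndarray
    pixel_pitch: float = DEFAULT_PIXEL_PITCH_UM
    bit_depth: int = 8

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"pixels must be a non-empty 2-D grid, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("pixel values must be integers")
            arr = np.round(arr).astype(np.int64)
        if self.bit_depth != 8:
            raise ValueError("only 8-bit images are supported")
        lo, hi = 0, (1 << self.bit_depth) - 1
        if arr.min() < lo or arr.max() > hi:
            raise ValueError(f"pixel values must lie in [{lo}, {hi}]")
        if not self.pixel_pitch > 0:
            raise ValueError("pixel_pitch must be positive")
        object.__setattr__(self, "pixels", arr.astype(np.uint8))
        self.pixels.setflags(write=False)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def as_float(self) -> np.ndarray:
        """Pixels as a float64 array (the working precision of all scoring)."""
        return self.pixels.astype(np.float64)


@dataclass(frozen=True)
class MeasurementSeries:
    """Replicate scalar readings for one (site, timepoint, instrument).

    ``values`` are positive reals: g·m⁻²·h⁻¹ for TEWL instruments,
    dimensionless relative permittivity for the imaging system.
    """

    site_id: str
    timepoint: str
    instrument: str
    values: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if len(vals) < 1:
            raise ValueError("a measurement series needs at least one value")
        if not all(np.isfinite(v) and v > 0 for v in vals):
            raise ValueError("all measurement values must be finite and > 0")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=np.float64)


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("png", "csv"):
            raise ValueError(f"unsupported image format {fmt!r}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("png", "csv"):
        return suffix
    raise ValueError(f"cannot infer image format from {path.name!r}; pass fmt=")


def read_image(path: str | Path, fmt: str | None = None) -> CapacitiveImage:
    """Read a capacitive frame from PNG or CSV, bit-exactly.

    PNG files must be single-channel 8-bit greyscale.  CSV files must be a
    rectangular headerless grid of integers in [0, 255].  Pixel pitch is
    taken from a ``<name>.meta.json`` sidecar when present, else the default.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    if fmt == "png":
        with Image.open(path) as im:
            if im.mode != "L":
                raise ValueError(
                    f"{path.name}: expected single-channel 8-bit PNG (mode 'L'), got mode {im.mode!r}"
                )
            arr = np.asarray(im, dtype=np.uint8)
    else:
        arr = _read_csv_grid(path)

    pitch = DEFAULT_PIXEL_PITCH_UM
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        pitch = float(meta.get("pixel_pitch_um", pitch))
    return CapacitiveImage(pixels=arr, pixel_pitch=pitch)


def _read_csv_grid(path: Path) -> np.ndarray:
    rows: list[list[int]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        cells = line.split(",")
        try:
            row = [int(c) for c in cells]
        except ValueError as exc:
            raise ValueError(f"{path.name}:{lineno}: non-integer cell") from exc
        rows.append(row)
    if not rows:
        raise ValueError(f"{path.name}: empty image grid")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path.name}: ragged CSV grid (row lengths {sorted(widths)})")
    arr = np.asarray(rows, dtype=np.int64)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError(f"{path.name}: grey values outside [0, 255]")
    return arr.astype(np.uint8)


def write_image(img: CapacitiveImage, path: str | Path, fmt: str | None = None) -> None:
    """Write a frame to PNG or CSV so that :func:`read_image` round-trips bit-exactly."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "png":
        Image.fromarray(img.pixels, mode="L").save(path, format="PNG")
    else:
        lines = [",".join(str(int(v)) for v in row) for row in img.pixels]
        path.write_text("\n".join(lines) + "\n")
    if img.pixel_pitch != DEFAULT_PIXEL_PITCH_UM:
        _sidecar_path(path).write_text(json.dumps({"pixel_pitch_um": img.pixel_pitch}))


def read_measurements(path: str | Path) -> list[MeasurementSeries]:
    """Read a replicate-measurement CSV into one series per group.

    One :class:`MeasurementSeries` is returned per distinct
    ``(site_id, timepoint, instrument)`` key, replicate order preserved
    (rows sorted by the ``replicate`` column within each group).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"site_id": str, "timepoint": str, "instrument": str})
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    if df.empty:
        return []
    values = pd.to_numeric(df["value"], errors="coerce")
    if values.isna().any():
        bad = int(df.index[values.isna()][0]) + 2  # header + 1-based
        raise ValueError(f"{path.name}: non-numeric value near line {bad}")
    df = df.assign(value=values)
    out: list[MeasurementSeries] = []
    for (site, tp, instr), grp in df.groupby(
        ["site_id", "timepoint", "instrument"], sort=False
    ):
        grp = grp.sort_values("replicate", kind="stable")
        out.append(
            MeasurementSeries(
                site_id=str(site),
                timepoint=str(tp),
                instrument=str(instr),
                values=tuple(grp["value"].tolist()),
            )
        )
    return out


def write_measurements(series: Iterable[MeasurementSeries], path: str | Path) -> None:
    """Write series to the measurement-CSV schema read by :func:`read_measurements`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in series:
        for rep, v in enumerate(s.values, start=1):
            rows.append((s.site_id, s.timepoint, s.instrument, rep, v))
    df = pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))
    df.to_csv(path, index=False)


def group_key(s: MeasurementSeries) -> tuple[str, str, str]:
    return (s.site_id, s.timepoint, s.instrument)
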