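"""Gridded environmental layers and ESRI ASCII grid (.asc) I/O.

A :class:`RasterStack` bundles co-registered layers on one lat/lon grid
(row 0 = northernmost row, origin at the upper-left cell corner, cell size
in arcminutes) together with a joint validity mask: any cell missing in
any layer is excluded from every downstream computation.

The plain-text ESRI ASCII grid format is written and read directly; it is
a six-line header (ncols, nrows, xllcorner, yllcorner, cellsize,
NODATA_value) followed by whitespace-separated rows, north first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["GeoMeta", "RasterStack", "read_asc", "write_asc"]

NODATA = -9999.0


@dataclass(frozen=True)
class GeoMeta:
    origin_lat: float          # latitude of the upper-left corner, degrees
    origin_lon: float          # longitude of the upper-left corner, degrees
    cellsize_arcmin: float     # cell size in arcminutes

    @property
    def cellsize_deg(self) -> float:
        return self.cellsize_arcmin / 60.0


@dataclass
class RasterStack:
    """Named layers on a shared grid plus a joint validity mask."""

    layers: dict[str, np.ndarray]
    geo: GeoMeta
    mask: np.ndarray = field(default=None)  # True = valid cell

    def __post_init__(self) -> None:
        shapes = {name: a.shape for name, a in self.layers.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"layers disagree on shape: {shapes}")
        if self.mask is None:
            self.mask = np.ones(self.shape, dtype=bool)
        if self.mask.shape != self.shape:
            raise ValueError("mask shape does not match layers")
        self.mask = self.mask.astype(bool)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def layer(self, name: str) -> np.ndarray:
        try:
            return self.layers[name]
        except KeyError:
            raise KeyError(
                f"missing layer {name!r}; available: {sorted(self.layers)}"
            ) from None

    def with_layers(self, **replacements: np.ndarray) -> "RasterStack":
        """Copy of the stack with some layers replaced."""
        new = dict(self.layers)
        for k, v in replacements.items():
            if v.shape != self.shape:
                raise ValueError(f"replacement layer {k!r} has wrong shape")
            new[k] = v
        return RasterStack(new, self.geo, self.mask.copy())

    # -- I/O --------------------------------------------------------------
    def write_dir(self, directory: str | Path) -> None:
        """One .asc file per layer; masked cells become NODATA."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, arr in self.layers.items():
            out = np.where(self.mask, arr, NODATA)
            write_asc(directory / f"{name}.asc", out, self.geo)

    @classmethod
    def read_dir(cls, directory: str | Path) -> "RasterStack":
        directory = Path(directory)
        files = sorted(directory.glob("*.asc"))
        if not files:
            raise FileNotFoundError(f"no .asc layers in {directory}")
        layers: dict[str, np.ndarray] = {}
        geo = None
        mask = None
        for f in files:
            arr, g = read_asc(f)
            layers[f.stem] = arr
            geo = g
            valid = arr != NODATA
            mask = valid if mask is None else (mask & valid)
        return cls(layers, geo, mask)


def write_asc(path: str | Path, array: np.ndarray, geo: GeoMeta) -> None:
    h, w = array.shape
    cell = geo.cellsize_deg
    yll = geo.origin_lat - h * cell
    header = (
        f"ncols {w}\n"
        f"nrows {h}\n"
        f"xllcorner {geo.origin_lon:.6f}\n"
        f"yllcorner {yll:.6f}\n"
        f"cellsize {cell:.6f}\n"
        f"NODATA_value {NODATA:g}\n"
    )
    body = "\n".join(" ".join(f"{v:.6g}" for v in row) for row in array)
    Path(path).write_text(header + body + "\n")


def read_asc(path: str | Path) -> tuple[np.ndarray, GeoMeta]:
    lines = Path(path).read_text().splitlines()
    hdr: dict[str, float] = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in {
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
    }:
        key, val = lines[i].split()
        hdr[key.lower()] = float(val)
        i += 1
    arr = np.array([[float(v) for v in ln.split()] for ln in lines[i:] if ln.strip()])
    h, w = int(hdr["nrows"]), int(hdr["ncols"])
    if arr.shape != (h, w):
        raise ValueError(f"grid body {arr.shape} disagrees with header ({h}, {w})")
    cell_deg = hdr["cellsize"]
    geo = GeoMeta(
        origin_lat=hdr["yllcorner"] + h * cell_deg,
        origin_lon=hdr["xllcorner"],
        cellsize_arcmin=cell_deg * 60.0,
    )
    return arr, geo
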