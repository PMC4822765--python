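"""Grid-raster container for habitat class maps.

All coordinates live in an abstract projected plane in meters; there is no
geographic CRS.  The grid is axis-aligned, row 0 of :attr:`GridRaster.data`
is the *southernmost* row (ESRI ASCII files, which store north-up, are
flipped on read/write).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Habitat class codes.  The five classes of a mangrove archipelago:
# open water / channels, Phoenix paludosa thicket on high dry ground,
# Ceriops decandra shrub, barren salt-encrusted flats, and low-lying
# Avicennia/Sonneratia silt banks.
WATER = 0
PHOENIX = 1
CERIOPS = 2
BARREN = 3
AVIC_SONN = 4

CLASS_NAMES: dict[int, str] = {
    WATER: "Water",
    PHOENIX: "Phoenix",
    CERIOPS: "Ceriops",
    BARREN: "Barren",
    AVIC_SONN: "AvicenniaSonneratia",
}
CLASS_CODES: dict[str, int] = {v: k for k, v in CLASS_NAMES.items()}
ALL_CLASSES: tuple[str, ...] = tuple(CLASS_NAMES[c] for c in sorted(CLASS_NAMES))


@dataclass
class GridRaster:
    """Integer class raster on a regular grid.

    Parameters
    ----------
    data
        ``(ny, nx)`` integer array, row 0 = southernmost row.
    x0, y0
        Coordinates of the lower-left corner (not cell center), meters.
    cell_size
        Cell edge length in meters.
    """

    data: np.ndarray
    x0: float
    y0: float
    cell_size: float
    nodata: int = -9999

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        ny, nx = self.data.shape
        return (self.x0, self.y0,
                self.x0 + nx * self.cell_size, self.y0 + ny * self.cell_size)

    def contains(self, x, y) -> np.ndarray:
        x0, y0, x1, y1 = self.extent
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= x0) & (x < x1) & (y >= y0) & (y < y1)

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices of the cells containing (x, y)."""
        ix = np.floor((np.asarray(x, dtype=float) - self.x0) / self.cell_size)
        iy = np.floor((np.asarray(y, dtype=float) - self.y0) / self.cell_size)
        return iy.astype(int), ix.astype(int)

    def value_at(self, x, y, outside: str = "raise") -> np.ndarray:
        """Class codes at points; ``outside`` is 'raise' or 'nodata'."""
        inside = self.contains(x, y)
        if outside == "raise" and not np.all(inside):
            bad = int(np.argmin(inside))
            raise ValueError(f"point index {bad} lies outside the raster extent")
        iy, ix = self.index_of(np.clip(x, *self._xclip()), np.clip(y, *self._yclip()))
        vals = self.data[iy, ix]
        if outside == "nodata":
            vals = np.where(inside, vals, self.nodata)
        return vals

    def _xclip(self):
        x0, _, x1, _ = self.extent
        return x0, np.nextafter(x1, x0)

    def _yclip(self):
        _, y0, _, y1 = self.extent
        return y0, np.nextafter(y1, y0)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.data.shape
        xs = self.x0 + (np.arange(nx) + 0.5) * self.cell_size
        ys = self.y0 + (np.arange(ny) + 0.5) * self.cell_size
        return xs, ys

    # -- summaries --------------------------------------------------------
    def class_fractions(self) -> dict[str, float]:
        """Realized fraction of cells per habitat class name."""
        total = self.data.size
        return {
            name: float(np.count_nonzero(self.data == code)) / total
            for code, name in CLASS_NAMES.items()
        }

    # -- I/O (ESRI ASCII grid) -------------------------------------------
    def write_ascii(self, path) -> None:
        ny, nx = self.data.shape
        header = (
            f"ncols {nx}\n"
            f"nrows {ny}\n"
            f"xllcorner {self.x0!r}\n"
            f"yllcorner {self.y0!r}\n"
            f"cellsize {self.cell_size!r}\n"
            f"NODATA_value {self.nodata}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.data[::-1], fmt="%d")

    @classmethod
    def read_ascii(cls, path) -> "GridRaster":
        meta: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                pos = fh.tell()
                parts = fh.readline().split()
                if len(parts) != 2 or not parts[0][0].isalpha():
                    fh.seek(pos)
                    break
                meta[parts[0].lower()] = float(parts[1])
            data = np.loadtxt(fh, dtype=int)
        data = np.atleast_2d(data)[::-1]
        if "xllcorner" not in meta or "yllcorner" not in meta:
            raise ValueError(f"{path}: missing xllcorner/yllcorner header")
        return cls(
            data=data,
            x0=meta["xllcorner"],
            y0=meta["yllcorner"],
            cell_size=meta["cellsize"],
            nodata=int(meta.get("nodata_value", -9999)),
        )
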