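"""Multi-layer climate raster container and plain-text IO.

The grid is row-major from the north-west corner: latitude decreases with
row index, longitude increases with column index. Pixel membership uses
half-open intervals [west, east) x (south, north] so every in-extent point
maps to exactly one pixel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: The twelve climate variables used throughout: WorldClim bioclim
#: temperature/precipitation layers, ENVIREM-style potential
#: evapotranspiration, elevation, climatic moisture, and cloud cover.
VARIABLE_CODES: tuple[str, ...] = (
    "BIO1", "BIO5", "BIO6", "BIO12", "BIO16", "BIO17",
    "PET.A", "PET.W", "PET.D", "Elev", "CM", "CC",
)


class RasterError(ValueError):
    """Raised for malformed raster geometry or layer mismatches."""


@dataclass
class ClimateRaster:
    """Aligned stack of climate layers with geographic metadata.

    Parameters
    ----------
    values
        Array of shape ``(n_vars, n_rows, n_cols)`` in each variable's
        native units.
    lon_origin, lat_origin
        Degrees of the grid's upper-left (north-west) pixel *corner*.
    pixel_size
        Pixel edge length in arc-minutes.
    validity_mask
        Boolean ``(n_rows, n_cols)`` array; ``False`` pixels carry no data.
    """

    values: np.ndarray
    lon_origin: float
    lat_origin: float
    pixel_size: float
    variable_codes: tuple[str, ...] = VARIABLE_CODES
    validity_mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise RasterError("values must be (n_vars, n_rows, n_cols)")
        if self.values.shape[0] != len(self.variable_codes):
            raise RasterError(
                f"{self.values.shape[0]} layers for "
                f"{len(self.variable_codes)} variable codes"
            )
        if self.pixel_size <= 0:
            raise RasterError("pixel_size must be positive arc-minutes")
        if self.validity_mask is None:
            self.validity_mask = np.ones(self.values.shape[1:], dtype=bool)
        self.validity_mask = np.asarray(self.validity_mask, dtype=bool)
        if self.validity_mask.shape != self.values.shape[1:]:
            raise RasterError("validity_mask shape does not match layers")

    # ------------------------------------------------------------------
    # geometry
    # ------------------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[1]

    @property
    def n_cols(self) -> int:
        return self.values.shape[2]

    @property
    def pixel_deg(self) -> float:
        return self.pixel_size / 60.0

    def layer(self, code: str) -> np.ndarray:
        try:
            idx = self.variable_codes.index(code)
        except ValueError:
            raise RasterError(f"unknown variable code {code!r}") from None
        return self.values[idx]

    def lonlat_to_rowcol(
        self, lon: np.ndarray, lat: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map coordinates to pixel indices.

        Returns ``(rows, cols, inside)`` where ``inside`` flags points
        within the extent. Longitudes use [west, east); latitudes use
        (south, north], so a point exactly on the northern origin edge is
        row 0 and a point on the southern outer edge is outside.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        u = (lon - self.lon_origin) / self.pixel_deg
        v = (self.lat_origin - lat) / self.pixel_deg
        cols = np.floor(u).astype(int)
        # (south, north] in latitude: v in [i, i+1) belongs to row i; a point
        # on a shared horizontal edge (v integer) is the north edge of row v.
        rows = np.floor(v).astype(int)
        inside = (
            (u >= 0) & (cols < self.n_cols) & (v >= 0) & (rows < self.n_rows)
        )
        rows = np.clip(rows, 0, self.n_rows - 1)
        cols = np.clip(cols, 0, self.n_cols - 1)
        return rows, cols, inside

    def pixel_center(
        self, rows: np.ndarray, cols: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Longitude/latitude of pixel centers."""
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        lon = self.lon_origin + (cols + 0.5) * self.pixel_deg
        lat = self.lat_origin - (rows + 0.5) * self.pixel_deg
        return lon, lat

    def latitudes(self) -> np.ndarray:
        """Latitude of each row's pixel centers (length n_rows)."""
        return self.lat_origin - (np.arange(self.n_rows) + 0.5) * self.pixel_deg

    def pixel_values(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Climate matrix ``(n_points, n_vars)`` at the given pixels."""
        return self.values[:, rows, cols].T

    def valid_pixel_matrix(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All valid pixels as ``(rows, cols, X)`` with X ``(n_valid, n_vars)``."""
        rows, cols = np.nonzero(self.validity_mask)
        return rows, cols, self.pixel_values(rows, cols)


# ----------------------------------------------------------------------
# plain-text grid bundle IO (one .txt grid per variable + metadata.json)
# ----------------------------------------------------------------------

def write_raster_text(raster: ClimateRaster, directory: str | Path) -> Path:
    """Write a raster as a plain-text grid bundle, readable back bit-exactly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "variable_codes": list(raster.variable_codes),
        "lon_origin": raster.lon_origin,
        "lat_origin": raster.lat_origin,
        "pixel_size": raster.pixel_size,
        "n_rows": raster.n_rows,
        "n_cols": raster.n_cols,
    }
    (directory / "metadata.json").write_text(json.dumps(meta, indent=1))
    for i, code in enumerate(raster.variable_codes):
        fname = directory / (code.replace(".", "_") + ".txt")
        np.savetxt(fname, raster.values[i], fmt="%.17g")
    np.savetxt(directory / "mask.txt", raster.validity_mask.astype(int), fmt="%d")
    return directory


def read_raster_text(directory: str | Path) -> ClimateRaster:
    directory = Path(directory)
    meta = json.loads((directory / "metadata.json").read_text())
    codes = tuple(meta["variable_codes"])
    layers = []
    for code in codes:
        fname = directory / (code.replace(".", "_") + ".txt")
        grid = np.loadtxt(fname, dtype=float, ndmin=2)
        layers.append(grid)
    mask = np.loadtxt(directory / "mask.txt", dtype=int, ndmin=2).astype(bool)
    return ClimateRaster(
        values=np.stack(layers),
        lon_origin=meta["lon_origin"],
        lat_origin=meta["lat_origin"],
        pixel_size=meta["pixel_size"],
        variable_codes=codes,
        validity_mask=mask,
    )
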