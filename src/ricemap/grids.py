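"""Raster grid container, unit tags, co-registration checks, and TIFF I/O.

All pipeline stages operate on :class:`Grid2D`: a 2-D array of values on a
regular ground grid with an explicit nodata mask and a physical-unit tag.
Unit tags are checked at operation boundaries so that, e.g., the dB
conversion cannot be applied twice or the phenology compositor fed linear
power by mistake.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import tifffile


class Unit(str, Enum):
    """Physical unit tag of a grid's values."""

    LINEAR_POWER = "linear-power"  # calibrated backscatter sigma-0, linear scale
    DB = "dB"                      # 10*log10(sigma-0)
    REFLECTANCE = "reflectance"    # surface reflectance, nominally [0, 1]
    INDEX = "index"                # dimensionless spectral index (NDVI)
    LABEL = "label"                # integer categorical labels


class UnitMismatchError(ValueError):
    """Operation applied to a grid with the wrong unit tag."""


class CoRegistrationError(ValueError):
    """Grids that must share a grid geometry do not."""


@dataclass
class Transform:
    """Affine geotransform of a north-up grid.

    ``x = origin_x + col * pixel_size``, ``y = origin_y - row * pixel_size``.
    """

    origin_x: float = 0.0
    origin_y: float = 0.0
    pixel_size: float = 30.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")

    def approx_equal(self, other: "Transform", tol: float = 1e-6) -> bool:
        return (
            abs(self.origin_x - other.origin_x) <= tol
            and abs(self.origin_y - other.origin_y) <= tol
            and abs(self.pixel_size - other.pixel_size) <= tol
        )


@dataclass
class Grid2D:
    """A single-band raster: values + nodata mask + geotransform + unit tag."""

    values: np.ndarray
    unit: Unit
    transform: Transform = field(default_factory=Transform)
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {self.values.shape}")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError(
                f"nodata_mask shape {self.nodata_mask.shape} != values shape {self.values.shape}"
            )
        self.unit = Unit(self.unit)

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_size(self) -> float:
        return self.transform.pixel_size

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    # -- helpers ----------------------------------------------------------
    def require_unit(self, unit: Unit) -> None:
        if self.unit != unit:
            raise UnitMismatchError(
                f"expected unit {unit.value!r}, got {self.unit.value!r}"
            )

    def with_values(self, values: np.ndarray, unit: Unit | None = None,
                    nodata_mask: np.ndarray | None = None) -> "Grid2D":
        """New grid on the same geometry with replaced values/unit/mask."""
        return Grid2D(
            values=np.asarray(values),
            unit=self.unit if unit is None else unit,
            transform=replace(self.transform),
            nodata_mask=self.nodata_mask.copy() if nodata_mask is None else nodata_mask,
        )


def check_coregistered(*grids: Grid2D, tol: float = 1e-6) -> None:
    """Raise :class:`CoRegistrationError` unless all grids share shape+transform."""
    if not grids:
        return
    first = grids[0]
    for g in grids[1:]:
        if g.shape != first.shape:
            raise CoRegistrationError(f"shape mismatch: {g.shape} vs {first.shape}")
        if not g.transform.approx_equal(first.transform, tol):
            raise CoRegistrationError("geotransform mismatch")


# ---------------------------------------------------------------------------
# TIFF I/O.  Geotransform, unit tag and nodata value travel in a JSON
# ImageDescription tag; nodata pixels are written as the nodata value.
# ---------------------------------------------------------------------------

_NODATA_FILL = -9999.0


def write_grid(path, grid: Grid2D) -> None:
    """Write a single-band grid as TIFF with JSON metadata sidecar tag."""
    write_bands(path, [grid], band_names=["band1"])


def write_bands(path, grids: list[Grid2D], band_names: list[str]) -> None:
    """Write co-registered grids as a multi-band TIFF."""
    check_coregistered(*grids)
    if len(grids) != len(band_names):
        raise ValueError("one band name per grid required")
    data = np.stack(
        [np.where(g.nodata_mask, _NODATA_FILL, g.values).astype(np.float64)
         for g in grids]
    )
    t = grids[0].transform
    meta = {
        "units": [g.unit.value for g in grids],
        "band_names": band_names,
        "nodata": _NODATA_FILL,
        "origin_x": t.origin_x,
        "origin_y": t.origin_y,
        "pixel_size": t.pixel_size,
    }
    tifffile.imwrite(str(path), data, photometric="minisblack",
                     description=json.dumps(meta))


def read_bands(path) -> tuple[list[Grid2D], list[str]]:
    """Read a TIFF written by :func:`write_bands`; returns (grids, band names)."""
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    meta = json.loads(desc)
    if data.ndim == 2:
        data = data[None]
    transform = Transform(meta["origin_x"], meta["origin_y"], meta["pixel_size"])
    grids = []
    for band, unit in zip(data, meta["units"]):
        mask = band == meta["nodata"]
        grids.append(Grid2D(band, Unit(unit), transform, nodata_mask=mask))
    return grids, list(meta["band_names"])


def read_grid(path) -> Grid2D:
    grids, _ = read_bands(path)
    if len(grids) != 1:
        raise ValueError(f"expected single-band file, got {len(grids)} bands")
    return grids[0]
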