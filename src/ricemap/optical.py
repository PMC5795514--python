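"""NDVI and the seasonal-contrast "cropland image".

Cropland in a double-cropping rice region is bare in winter and green in
the growing season, whereas forest stays green year-round and water stays
non-vegetated.  Stacking the growing-season NDVI maximum, the winter NDVI
minimum and their difference therefore separates cropland (large
difference) from forest (small difference, high maximum) and everything
else.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .grids import Grid2D, Unit, check_coregistered
from .temporal import EnhancedImage


@dataclass
class OpticalPair:
    """Co-registered red and near-infrared reflectance grids for one date."""

    red: Grid2D
    nir: Grid2D
    date: dt.date

    def __post_init__(self) -> None:
        self.red.require_unit(Unit.REFLECTANCE)
        self.nir.require_unit(Unit.REFLECTANCE)
        check_coregistered(self.red, self.nir)


def ndvi(pair: OpticalPair) -> Grid2D:
    """Normalized Difference Vegetation Index (nir - red)/(nir + red).

    Pixels where the denominator is zero become nodata; output is clipped
    to [-1, 1] to absorb atmospheric-correction overshoot.
    """
    red = np.asarray(pair.red.values, float)
    nir = np.asarray(pair.nir.values, float)
    denom = nir + red
    zero = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (nir - red) / np.where(zero, 1.0, denom)
    out = np.clip(out, -1.0, 1.0)
    mask = pair.red.nodata_mask | pair.nir.nodata_mask | zero
    out[mask] = np.nan
    return pair.red.with_values(out, unit=Unit.INDEX, nodata_mask=mask)


def build_cropland_image(growing_ndvi: list[Grid2D],
                         winter_ndvi: list[Grid2D]) -> EnhancedImage:
    """Growing-season NDVI maximum, winter NDVI minimum, and difference.

    Unlike the SAR enhanced image the difference band here pairs the
    growing-season max with the winter min, so it is not guaranteed
    non-negative (e.g. turbid winter water); the classifier, not a clamp,
    handles such pixels.
    """
    if not growing_ndvi or not winter_ndvi:
        raise ValueError("growing and winter NDVI lists must be non-empty")
    for g in growing_ndvi + winter_ndvi:
        g.require_unit(Unit.INDEX)
    check_coregistered(*(growing_ndvi + winter_ndvi))

    def reduce(grids: list[Grid2D], fn) -> Grid2D:
        cube = np.stack([np.where(g.nodata_mask, np.nan, np.asarray(g.values, float))
                         for g in grids])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels
            out = fn(cube, axis=0)
        mask = np.isnan(out)
        return grids[0].with_values(np.where(mask, np.nan, out), nodata_mask=mask)

    band_max = reduce(growing_ndvi, np.nanmax)
    band_min = reduce(winter_ndvi, np.nanmin)
    mask = band_min.nodata_mask | band_max.nodata_mask
    diff = np.where(mask, np.nan, band_max.values - band_min.values)
    band_diff = band_min.with_values(diff, nodata_mask=mask)
    return EnhancedImage(band_min, band_max, band_diff)


class CroplandEnhancer(BaseEstimator, TransformerMixin):
    """Transformer from dated optical pairs to the 3-band cropland image.

    Parameters
    ----------
    growing_dates, winter_dates : lists of datetime.date
        Which acquisition dates count as green-season vs bare-winter.
    """

    def __init__(self, growing_dates: list[dt.date] | None = None,
                 winter_dates: list[dt.date] | None = None):
        self.growing_dates = growing_dates
        self.winter_dates = winter_dates

    def fit(self, X, y=None):
        return self

    def transform(self, X: list[OpticalPair]) -> EnhancedImage:
        growing = set(self.growing_dates or [])
        winter = set(self.winter_dates or [])
        unknown = {p.date for p in X} - growing - winter
        if self.growing_dates is None and self.winter_dates is None:
            raise ValueError("growing_dates and winter_dates must be configured")
        if unknown:
            raise ValueError(f"dates not tagged growing or winter: {sorted(unknown)}")
        g = [ndvi(p) for p in X if p.date in growing]
        w = [ndvi(p) for p in X if p.date in winter]
        return build_cropland_image(g, w)
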