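"""SAR radiometry on the analysis grid: dB conversion, speckle suppression,
nearest-neighbour resampling.

These are the grid-level preprocessing steps applied to each calibrated
backscatter acquisition before temporal compositing: sigma-0 in linear power
is converted to decibels (10*log10), speckle is suppressed with a 5x5 moving
median, and grids are resampled to the common 30 m analysis resolution by
nearest neighbour.  A :class:`SarPreprocessor` estimator chains the three.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .grids import Grid2D, Transform, Unit


def to_decibel(sigma0: Grid2D) -> Grid2D:
    """Convert linear-power backscatter to decibels, 10*log10(sigma0).

    Pixels with sigma0 <= 0 (present in real calibrated products) become
    nodata rather than raising.
    """
    sigma0.require_unit(Unit.LINEAR_POWER)
    vals = np.asarray(sigma0.values, dtype=float)
    nonpositive = vals <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        db = 10.0 * np.log10(np.where(nonpositive, 1.0, vals))
    db[nonpositive] = np.nan
    mask = sigma0.nodata_mask | nonpositive
    return sigma0.with_values(db, unit=Unit.DB, nodata_mask=mask)


def from_decibel(db: Grid2D) -> Grid2D:
    """Inverse of :func:`to_decibel`: 10**(x/10)."""
    db.require_unit(Unit.DB)
    return db.with_values(np.power(10.0, np.asarray(db.values, float) / 10.0),
                          unit=Unit.LINEAR_POWER)


def despeckle_median(grid: Grid2D, window: int = 5) -> Grid2D:
    """Moving-median speckle filter.

    Each valid pixel becomes the median of the ``window x window``
    neighbourhood centred on it, computed over valid pixels only.  Borders
    use reflect padding.  Nodata pixels stay nodata; a pixel whose whole
    window is nodata also becomes nodata.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    rows, cols = grid.shape
    if rows < window or cols < window:
        raise ValueError(
            f"grid {grid.shape} smaller than filter window {window}"
        )
    half = window // 2
    vals = np.where(grid.nodata_mask, np.nan, np.asarray(grid.values, float))
    padded = np.pad(vals, half, mode="reflect")
    windows = np.lib.stride_tricks.sliding_window_view(padded, (window, window))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        med = np.nanmedian(windows, axis=(2, 3))
    all_nan = np.isnan(med)
    out_mask = grid.nodata_mask | all_nan
    med = np.where(out_mask, np.nan, med)
    # nodata pixels themselves stay nodata regardless of neighbours
    return grid.with_values(med, nodata_mask=out_mask)


def resample_nearest(grid: Grid2D, target_pixel_size: float) -> Grid2D:
    """Resample onto ``target_pixel_size`` by nearest source-pixel centre.

    Output covers the same extent; dimensions are ``ceil(src * src_size /
    target_size)``.  Equidistant ties resolve to the smaller row index, then
    the smaller column index.  Unit tag is preserved and no new values are
    invented.
    """
    if target_pixel_size <= 0:
        raise ValueError(f"target pixel size must be positive, got {target_pixel_size}")
    src = grid.transform.pixel_size
    if target_pixel_size == src:
        return grid.with_values(grid.values.copy())
    rows, cols = grid.shape
    out_rows = int(np.ceil(rows * src / target_pixel_size))
    out_cols = int(np.ceil(cols * src / target_pixel_size))

    def nearest_index(n_out: int, n_src: int) -> np.ndarray:
        centers = (np.arange(n_out) + 0.5) * target_pixel_size
        src_centers = (np.arange(n_src) + 0.5) * src
        dist = np.abs(centers[:, None] - src_centers[None, :])
        # argmin returns the first (smallest-index) minimum: the stated tie-break
        return np.argmin(dist, axis=1)

    ri = nearest_index(out_rows, rows)
    ci = nearest_index(out_cols, cols)
    values = grid.values[np.ix_(ri, ci)]
    mask = grid.nodata_mask[np.ix_(ri, ci)]
    t = grid.transform
    return Grid2D(values, grid.unit,
                  Transform(t.origin_x, t.origin_y, target_pixel_size),
                  nodata_mask=mask)


class SarPreprocessor(BaseEstimator, TransformerMixin):
    """dB conversion + median despeckling + nearest-neighbour resampling.

    A stateless transformer (``fit`` is a no-op) so the preprocessing chain
    composes with scikit-learn pipelines.  ``transform`` accepts a single
    :class:`Grid2D` or a list of them.

    Parameters
    ----------
    window : int
        Median-filter window edge, odd, default 5.
    target_pixel_size : float or None
        Analysis resolution in metres (default 30); ``None`` skips resampling.
    convert_db : bool
        Convert linear power to dB first; set False if input is already dB.
    """

    def __init__(self, window: int = 5, target_pixel_size: float | None = 30.0,
                 convert_db: bool = True):
        self.window = window
        self.target_pixel_size = target_pixel_size
        self.convert_db = convert_db

    def fit(self, X, y=None):  # noqa: D102 - stateless
        return self

    def _transform_one(self, grid: Grid2D) -> Grid2D:
        if self.convert_db:
            grid = to_decibel(grid)
        grid = despeckle_median(grid, self.window)
        if self.target_pixel_size is not None:
            grid = resample_nearest(grid, self.target_pixel_size)
        return grid

    def transform(self, X):
        if isinstance(X, Grid2D):
            return self._transform_one(X)
        return [self._transform_one(g) for g in X]
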