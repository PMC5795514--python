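"""Phenology-window compositing and the 3-band enhanced image."""

import datetime as dt

import numpy as np
import pytest

from ricemap import (AcquisitionStack, DateWindow, Grid2D, PhenologyCalendar,
                     PhenologyEnhancer, Transform, Unit, UnitMismatchError,
                     WindowCoverageError, build_enhanced_image,
                     window_composite)
from ricemap.synthetic import GEN_CODE


def stack_from_series(series, start=dt.date(2016, 3, 31), step=12,
                      unit=Unit.DB):
    """1x1 stack whose pixel takes the listed values date by date."""
    dates = [start + dt.timedelta(days=step * k) for k in range(len(series))]
    grids = [Grid2D(np.array([[v]], float), unit, Transform()) for v in series]
    return AcquisitionStack(dates, grids)


FULL = DateWindow(dt.date(2016, 1, 1), dt.date(2016, 12, 31))


class TestWindowComposite:
    def test_min_max_of_pixel_series(self):
        stack = stack_from_series([-12.0, -18.0, -15.0, -9.0])
        assert window_composite(stack, FULL, "min").values[0, 0] == -18.0
        assert window_composite(stack, FULL, "max").values[0, 0] == -9.0

    def test_constant_water_pixel_flat_for_both_reducers(self):
        stack = stack_from_series([-24.0] * 4)
        for reducer in ("min", "max"):
            assert window_composite(stack, FULL, reducer).values[0, 0] == -24.0

    def test_closed_window_includes_both_endpoints(self):
        stack = stack_from_series([-20.0, -10.0], step=36)
        window = DateWindow(stack.dates[0], stack.dates[1])
        assert window_composite(stack, window, "min").values[0, 0] == -20.0
        assert window_composite(stack, window, "max").values[0, 0] == -10.0

    def test_empty_window_raises_coverage_error(self):
        stack = stack_from_series([-12.0, -14.0])
        gap = DateWindow(dt.date(2016, 12, 1), dt.date(2016, 12, 31))
        with pytest.raises(WindowCoverageError):
            window_composite(stack, gap, "min")

    def test_nodata_observations_ignored_unless_all_missing(self):
        dates = [dt.date(2016, 4, d) for d in (1, 13, 25)]
        mk = lambda v, bad: Grid2D(np.array([[v]]), Unit.DB, Transform(),
                                   nodata_mask=np.array([[bad]]))
        stack = AcquisitionStack(dates, [mk(-12, False), mk(-30, True),
                                         mk(-15, False)])
        out = window_composite(stack, FULL, "min")
        assert out.values[0, 0] == -15.0
        all_bad = AcquisitionStack(dates, [mk(0, True)] * 3)
        assert window_composite(all_bad, FULL, "min").nodata_mask[0, 0]


class TestEnhancedImage:
    @pytest.mark.parametrize("level", [-24.0, -10.0])
    def test_flat_cover_gives_zero_difference(self, level):
        stack = stack_from_series([level] * 18)
        img = build_enhanced_image(stack, PhenologyCalendar(), "early")
        assert img.band_min.values[0, 0] == level
        assert img.band_max.values[0, 0] == level
        assert img.band_diff.values[0, 0] == 0.0

    def test_rice_pixel_min_max_diff(self, small_scene):
        # oracle: direct min/max over the generator's own series at a rice pixel
        img = build_enhanced_image(small_scene.sar, PhenologyCalendar(), "early")
        cal = PhenologyCalendar()
        r, c = map(int, np.argwhere(small_scene.truth.early_mask)[0])
        series = {d: g.values[r, c] for d, g in zip(small_scene.sar.dates,
                                                    small_scene.sar.grids)}
        early = [v for d, v in series.items()
                 if cal.early_growth("early").contains(d)]
        middle = [v for d, v in series.items()
                  if cal.middle_growth("early").contains(d)]
        assert img.band_min.values[r, c] == pytest.approx(min(early))
        assert img.band_max.values[r, c] == pytest.approx(max(middle))
        assert img.band_diff.values[r, c] == pytest.approx(max(middle) - min(early))

    def test_difference_invariant_to_constant_offset(self):
        series = [-12.0, -18.0, -15.0, -9.0, -11.0, -13.0]
        base = build_enhanced_image(stack_from_series(series),
                                    PhenologyCalendar(), "early")
        shifted = build_enhanced_image(stack_from_series([v + 3.5 for v in series]),
                                       PhenologyCalendar(), "early")
        assert shifted.band_diff.values[0, 0] == pytest.approx(
            base.band_diff.values[0, 0])

    def test_requires_db_stack(self):
        stack = stack_from_series([0.1] * 18, unit=Unit.LINEAR_POWER)
        with pytest.raises(UnitMismatchError):
            build_enhanced_image(stack, PhenologyCalendar(), "early")

    @pytest.mark.parametrize("rice_type", ["early", "middle", "late"])
    def test_rice_has_strongest_difference_contrast(self, small_scene, rice_type):
        """Mean difference over rice pixels exceeds water and forest means."""
        img = PhenologyEnhancer(rice_type).transform(small_scene.sar)
        labels = small_scene.truth.class_labels.values
        diff = img.band_diff.values
        rice_cls = ("cropland_early_late" if rice_type != "middle"
                    else "cropland_middle")
        rice_mean = diff[labels == GEN_CODE[rice_cls]].mean()
        assert rice_mean > diff[labels == GEN_CODE["water"]].mean() + 3
        assert rice_mean > diff[labels == GEN_CODE["forest_builtup"]].mean() + 3

    def test_min_composite_below_max_composite_same_window(self):
        stack = stack_from_series([-12.0, -18.0, -15.0, -9.0])
        lo = window_composite(stack, FULL, "min").values
        hi = window_composite(stack, FULL, "max").values
        assert (lo <= hi).all()


class TestPhenologyCalendar:
    def test_printed_early_rice_windows_are_default(self):
        cal = PhenologyCalendar()
        assert cal.early_growth("early") == DateWindow(dt.date(2016, 3, 31),
                                                       dt.date(2016, 5, 6))
        assert cal.middle_growth("early") == DateWindow(dt.date(2016, 5, 18),
                                                        dt.date(2016, 7, 17))

    def test_config_roundtrip_and_override(self):
        cal = PhenologyCalendar.from_dict({
            "early": {"early_growth": ["2016-04-01", "2016-05-01"],
                      "middle_growth": ["2016-05-20", "2016-07-10"]},
        })
        assert cal.early_growth("early").start == dt.date(2016, 4, 1)
        assert PhenologyCalendar.from_dict(cal.to_dict()).to_dict() == cal.to_dict()

    def test_missing_window_rejected(self):
        with pytest.raises(ValueError):
            PhenologyCalendar({"early": {"early_growth": FULL}})

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError):
            DateWindow(dt.date(2016, 6, 1), dt.date(2016, 5, 1))
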