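"""Error-matrix construction and design-based area/accuracy estimation."""

import numpy as np
import pytest

from ricemap import (ErrorMatrix, StratifiedAreaEstimator, accuracies,
                     adjusted_area, build_error_matrix, confidence_interval,
                     kappa, proportion_matrix, proportion_se, season_shares)
from ricemap.accuracy import UndefinedStratumError
from ricemap.fusion import LABEL_OF, CategoricalMap
from ricemap.grids import Grid2D, Transform, Unit
from ricemap.validation import stratified_bootstrap_se


def cat_map(names):
    codes = np.vectorize(LABEL_OF.get)(np.asarray(names))
    return CategoricalMap(Grid2D(codes.astype(int), Unit.LABEL, Transform()))


class TestBuildErrorMatrix:
    def test_identical_maps_give_diagonal(self):
        m = cat_map([["water", "forest"], ["other", "other"]])
        em = build_error_matrix(m, m, ["water", "forest", "other"])
        assert np.trace(em.counts) == em.n == 4
        assert em.counts[0, 0] == 1 and em.counts[2, 2] == 2

    def test_direct_tally_of_confusions(self):
        mapped = cat_map([["water"] * 2 + ["forest"] * 2] * 2)
        ref = cat_map([["water", "forest", "forest", "forest"]] * 2)
        em = build_error_matrix(mapped, ref, ["water", "forest"])
        assert em.counts.tolist() == [[2, 2], [0, 4]]

    def test_mapped_areas_and_total_from_full_map(self):
        mapped = cat_map([["water", "water"], ["forest", "other"]])
        em = build_error_matrix(mapped, mapped, ["water", "forest", "other"])
        px = 30.0**2 / 1e6
        np.testing.assert_allclose(em.mapped_areas, [2 * px, px, px])
        assert em.total_area == pytest.approx(4 * px)

    def test_label_outside_legend_rejected(self):
        mapped = cat_map([["water", "late_rice"]])
        with pytest.raises(KeyError):
            build_error_matrix(mapped, mapped, ["water", "forest"])

    def test_sample_mask_restricts_counts_not_areas(self):
        mapped = cat_map([["water", "water"], ["forest", "forest"]])
        sample = np.array([[True, False], [True, False]])
        em = build_error_matrix(mapped, mapped, ["water", "forest"],
                                sample_mask=sample)
        assert em.n == 2
        assert em.mapped_areas.sum() == pytest.approx(em.total_area)


class TestWorkedToyMatrix:
    """Hand-checked 2x2 example: counts [[45,5],[10,40]], areas (60,40)/100 km2."""

    def test_proportion_matrix_values(self, toy_error_matrix):
        pm = proportion_matrix(toy_error_matrix)
        np.testing.assert_allclose(pm.p, [[0.54, 0.06], [0.08, 0.32]],
                                   atol=1e-12)
        assert pm.column_totals[0] == pytest.approx(0.62)
        assert pm.p.sum() == pytest.approx(1.0)

    def test_adjusted_area(self, toy_error_matrix):
        pm = proportion_matrix(toy_error_matrix)
        np.testing.assert_allclose(adjusted_area(pm, 100.0), [62.0, 38.0])

    def test_standard_error_closed_form(self, toy_error_matrix):
        # direct evaluation: sqrt(0.36*0.9*0.1/49 + 0.16*0.2*0.8/49)
        se = proportion_se(toy_error_matrix)
        assert se[0] == pytest.approx(0.034405, abs=5e-7)

    def test_standard_error_agrees_with_stratified_bootstrap(self,
                                                             toy_error_matrix):
        se = proportion_se(toy_error_matrix)
        boot = stratified_bootstrap_se(toy_error_matrix, n_boot=4000, seed=0)
        np.testing.assert_allclose(boot, se, rtol=0.10)

    def test_doubling_counts_shrinks_se_by_known_factor(self, toy_error_matrix):
        doubled = ErrorMatrix(toy_error_matrix.counts * 2,
                              toy_error_matrix.categories,
                              toy_error_matrix.mapped_areas,
                              toy_error_matrix.total_area)
        ratio = proportion_se(doubled) / proportion_se(toy_error_matrix)
        np.testing.assert_allclose(ratio, np.sqrt(49 / 99), rtol=1e-12)

    def test_accuracies(self, toy_error_matrix):
        user, producer, overall = accuracies(proportion_matrix(toy_error_matrix))
        assert user[0] == pytest.approx(0.54 / 0.60)
        assert producer[0] == pytest.approx(0.54 / 0.62)
        assert overall == pytest.approx(0.86)

    def test_kappa(self, toy_error_matrix):
        # p_o = 0.85, p_e = (50*55 + 50*45)/100^2 = 0.5 -> kappa = 0.70
        assert kappa(toy_error_matrix) == pytest.approx(0.70)


class TestDegenerateMatrices:
    def test_perfect_diagonal(self):
        em = ErrorMatrix(np.diag([30, 70]), ["A", "B"],
                         np.array([30.0, 70.0]), 100.0)
        pm = proportion_matrix(em)
        np.testing.assert_allclose(np.diag(pm.p), [0.3, 0.7])
        np.testing.assert_allclose(proportion_se(em), [0.0, 0.0])
        np.testing.assert_allclose(adjusted_area(pm, 100.0), em.mapped_areas)
        assert kappa(em) == pytest.approx(1.0)
        user, producer, overall = accuracies(pm)
        assert overall == 1.0 and (user == 1.0).all()

    def test_independent_rows_give_zero_kappa(self):
        em = ErrorMatrix(np.array([[25, 25], [25, 25]]), ["A", "B"],
                         np.array([50.0, 50.0]), 100.0)
        assert kappa(em) == pytest.approx(0.0, abs=1e-12)

    def test_empty_stratum_with_area_rejected(self):
        em = ErrorMatrix(np.array([[10, 0], [0, 0]]), ["A", "B"],
                         np.array([60.0, 40.0]), 100.0)
        with pytest.raises(UndefinedStratumError):
            proportion_matrix(em)

    def test_single_sample_stratum_has_no_variance(self):
        em = ErrorMatrix(np.array([[1, 0], [0, 50]]), ["A", "B"],
                         np.array([60.0, 40.0]), 100.0)
        with pytest.raises(UndefinedStratumError):
            proportion_se(em)

    def test_zero_area_category_has_undefined_not_zero_accuracy(self):
        em = ErrorMatrix(np.array([[50, 0], [0, 0]]), ["A", "B"],
                         np.array([100.0, 0.0]), 100.0)
        user, producer, overall = accuracies(proportion_matrix(em))
        assert np.isnan(user[1]) and np.isnan(producer[1])


class TestConfidenceInterval:
    def test_halfwidth_formula(self):
        assert confidence_interval(9000.0, 0.0033) == pytest.approx(58.212)

    def test_zero_se_gives_zero(self):
        assert confidence_interval(1234.0, 0.0) == 0.0

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            confidence_interval(100.0, -0.1)


class TestSeasonShares:
    def test_total_grouping(self):
        shares = season_shares({"early_rice": 1588.39, "middle_rice": 592.15,
                                "late_rice": 3152.73}, "total")
        assert shares["middle_rice"] == pytest.approx(11.10, abs=0.005)
        assert shares["late_rice"] == pytest.approx(59.11, abs=0.005)
        assert sum(shares.values()) == pytest.approx(100.0)

    def test_early_season_grouping(self):
        shares = season_shares({"early_rice": 1630.84, "middle_rice": 556.21},
                               "early_season")
        assert shares["early_rice"] == pytest.approx(74.57, abs=0.005)
        assert shares["middle_rice"] == pytest.approx(25.43, abs=0.005)

    def test_single_area_is_hundred_percent(self):
        assert season_shares({"early_rice": 5.0}, "total") == {"early_rice": 100.0}

    def test_zero_group_sum_rejected(self):
        with pytest.raises(ValueError):
            season_shares({"early_rice": 0.0}, "total")


class TestStratifiedAreaEstimator:
    def test_fitted_attributes_consistent(self, toy_error_matrix):
        est = StratifiedAreaEstimator().fit(toy_error_matrix)
        np.testing.assert_allclose(est.adjusted_area_km2_, [62.0, 38.0])
        np.testing.assert_allclose(
            est.ci_halfwidth_km2_, 1.96 * 100.0 * est.se_proportion_)
        assert est.overall_accuracy_ == pytest.approx(0.86)
        assert est.kappa_ == pytest.approx(0.70)
        # adjusted areas of an exhaustive legend always total the map area
        assert est.adjusted_area_km2_.sum() == pytest.approx(100.0)

    def test_report_roundtrip(self, toy_error_matrix, tmp_path):
        import json
        est = StratifiedAreaEstimator().fit(toy_error_matrix)
        est.write_report(tmp_path / "r.csv", tmp_path / "r.json")
        with open(tmp_path / "r.json") as fh:
            payload = json.load(fh)
        assert payload["overall_accuracy"] == pytest.approx(0.86)
        assert payload["per_category"][0]["adjusted_area_km2"] == pytest.approx(62.0)

    def test_get_params_sklearn_contract(self):
        est = StratifiedAreaEstimator()
        assert "confidence_z" in est.get_params()
        est.set_params(confidence_z=1.645)
        assert est.confidence_z == 1.645
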