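"""Poisson partition statistics against a root-finding oracle, CI coverage,
fold/ratio/correlation summaries of the packaged survey, and cell volumes."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from ciliate_rdna.copy_number import (
    CellGeometry,
    CopyNumberEstimate,
    PartitionData,
    SaturationError,
    StandardCurve,
    cell_volume,
    dpcr_copies_per_cell,
    dpcr_lambda,
    fold_range,
    load_reference_survey,
    marker_comparison,
    marker_ratio,
    pearson_r,
    qpcr_copies,
    summarize_copy_numbers,
)
from ciliate_rdna.synthetic_data import DpcrSimSpec, simulate_dpcr


class TestDpcrLambda:
    def test_closed_forms(self):
        assert dpcr_lambda(0, 10_000) == 0
        assert dpcr_lambda(5000, 10_000) == pytest.approx(math.log(2), rel=1e-12)

    def test_matches_numeric_inversion_for_all_small_counts(self):
        # independent oracle: solve 1 - exp(-lam) = k/n by root finding
        for n in range(2, 21):
            for k in range(1, n):
                oracle = brentq(lambda lam: 1 - math.exp(-lam) - k / n, 1e-12, 60)
                assert dpcr_lambda(k, n) == pytest.approx(oracle, rel=1e-9), (k, n)

    def test_strictly_increasing_in_positives(self):
        lams = [dpcr_lambda(k, 1000) for k in range(0, 1000)]
        assert all(b > a for a, b in zip(lams, lams[1:]))

    def test_saturation_and_domain_errors(self):
        with pytest.raises(SaturationError):
            dpcr_lambda(100, 100)
        with pytest.raises(ValueError):
            dpcr_lambda(101, 100)


class TestDpcrCopiesPerCell:
    def test_zero_positives_gives_zero_with_zero_lower_bound(self):
        est = dpcr_copies_per_cell(PartitionData(10_000, 0))
        assert est.copies_per_cell == 0 and est.ci_low == 0

    def test_doubling_dilution_doubles_estimate(self):
        one = dpcr_copies_per_cell(PartitionData(10_000, 4000, 0.5, 2.0))
        two = dpcr_copies_per_cell(PartitionData(10_000, 4000, 0.5, 4.0))
        assert two.copies_per_cell == pytest.approx(2 * one.copies_per_cell)
        assert two.ci_high == pytest.approx(2 * one.ci_high)

    def test_ci_orders_and_estimate_inside(self):
        est = dpcr_copies_per_cell(PartitionData(25_000, 12_000, 0.5, 2.7))
        assert 0 < est.ci_low < est.copies_per_cell < est.ci_high

    def test_ci_coverage_is_nominal_over_500_replicates(self):
        # the module-level contract: 95% Wilson interval covers the true
        # per-cell copy number in 93-97% of simulated reactions
        truth = 8.1e5
        covered = 0
        n = 500
        for seed in range(1, n + 1):
            data = simulate_dpcr(
                DpcrSimSpec(truth, 25_000, fraction_loaded=0.5, dilution_factor=2.7, seed=seed)
            )
            est = dpcr_copies_per_cell(data)
            covered += est.ci_low <= truth <= est.ci_high
        assert 0.93 <= covered / n <= 0.97

    @pytest.mark.parametrize("truth", [1e4, 1e5, 1e6])
    def test_estimator_consistency_across_magnitudes(self, truth):
        dilution = max(1.0, 0.5 * truth / (1.5 * 25_000))
        ests = [
            dpcr_copies_per_cell(
                simulate_dpcr(
                    DpcrSimSpec(truth, 25_000, fraction_loaded=0.5,
                                dilution_factor=dilution, seed=s)
                )
            ).copies_per_cell
            for s in range(1, 41)
        ]
        assert abs(np.mean(ests) / truth - 1) < 0.03


class TestQpcr:
    def test_intercept_is_one_copy(self):
        curve = StandardCurve(slope=-3.32, intercept=38.0)
        assert qpcr_copies(38.0, curve) == pytest.approx(1.0)
        assert qpcr_copies(38.0 - 3.32 * 5, curve) == pytest.approx(1e5, rel=1e-9)

    def test_efficiency_from_slope(self):
        assert StandardCurve(slope=-3.3219, intercept=38).efficiency == pytest.approx(1.0, abs=1e-3)
        with pytest.raises(ValueError):
            StandardCurve(slope=0.5, intercept=38)


class TestFoldAndRatios:
    def test_published_endpoint_folds(self):
        # mitochondrial marker range endpoints across the surveyed classes
        assert fold_range([1.0e4, 1.1e5, 1.5e5, 8.1e5]) == pytest.approx(81.0)
        survey = load_reference_survey()
        spiro = survey.loc[survey["classification"] == "Spirotrichea", "mtssu_mean"]
        assert len(spiro) == 6
        assert fold_range(spiro) == pytest.approx(5.17, abs=0.01)  # "about 5-fold"

    def test_fold_range_properties_and_errors(self):
        assert fold_range([3.0, 3.0, 3.0]) == 1
        assert fold_range([2.0, 5.0]) >= 1
        with pytest.raises(ValueError):
            fold_range([1.0, 0.0])
        with pytest.raises(ValueError):
            fold_range([])

    def test_marker_ratio(self):
        assert marker_ratio(1.1e6, 8.4e4) == pytest.approx(13.095, abs=0.001)
        assert round(marker_ratio(1.1e6, 8.4e4)) == 13
        assert marker_ratio(5.0, 5.0) == 1
        with pytest.raises(ValueError):
            marker_ratio(-1, 2)


class TestPearson:
    def test_perfect_correlations(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_r(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)
        assert pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_survey_markers_weakly_correlated(self):
        r = marker_comparison(load_reference_survey())["mt_vs_nssu_pearson_r"]
        assert abs(r - 0.126) < 0.1  # weak, non-significant association

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCellVolume:
    def test_closed_forms(self):
        cuboid = CellGeometry(2, 3, 1.0, "cuboid")
        assert cuboid.thickness == 3  # ratio 1 -> thickness = width
        assert cell_volume(CellGeometry(2, 3, 3 / 4, "cuboid")) == pytest.approx(24.0)
        assert cell_volume(CellGeometry(3, 2, 1.0, "bell_cone")) == pytest.approx(math.pi)

    def test_bell_cone_is_pi_twelfths_of_cuboid(self):
        g_cub = CellGeometry(5, 4, 2.0, "cuboid")
        g_bell = CellGeometry(5, 4, 2.0, "bell_cone")
        assert cell_volume(g_bell) / cell_volume(g_cub) == pytest.approx(math.pi / 12)


class TestSummaries:
    def test_survey_column_extremes_and_ratio_count(self):
        cmp = marker_comparison(load_reference_survey())
        assert cmp["mtssu_min"] == pytest.approx(1.0e4)
        assert cmp["mtssu_max"] == pytest.approx(8.1e5)
        assert cmp["nssu_max"] == pytest.approx(1.1e6)
        assert cmp["nssu_min"] == pytest.approx(5.8e3)
        assert cmp["nssu_max_species"] == "Sterkiella_sp"
        assert cmp["nssu_min_species"] == "Coleps_sp"
        assert cmp["n_nssu_below_mtssu"] == 3

    def test_per_species_mean_sd_and_degenerate_group(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "species": ["a", "a", "a", "b"],
                "copies_per_cell": [1e4, 2e4, 4e4, 3e5],
            }
        )
        out = summarize_copy_numbers(df).set_index("species")
        assert out.loc["a", "mean"] == pytest.approx(7e4 / 3)
        assert out.loc["a", "intra_fold_range"] == pytest.approx(4.0)
        assert out.loc["b", "sd"] is None or np.isnan(out.loc["b", "sd"])
        assert out.loc["b", "intra_fold_range"] is None or np.isnan(out.loc["b", "intra_fold_range"])


def test_copy_number_estimate_validates_ordering():
    with pytest.raises(ValueError):
        CopyNumberEstimate(copies_per_cell=10, ci_low=20, ci_high=30, method="dPCR")
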