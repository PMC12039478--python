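"""Bottleneck estimation pipeline: filtering, fits, sweeps, ratios."""

import numpy as np
import pandas as pd
import pytest

from bgbottleneck.estimation import (ALLEN_SNR_TABLE, RegionCatalog,
                                     SourceNucleusParams, TracerExperiment,
                                     arborization_weighted_neurons,
                                     detect_asymptote, extrapolate_to_source,
                                     filter_targets, fit_scaling_model,
                                     per_experiment_ratio,
                                     proportion_of_source_injected,
                                     ratio_sweep, read_catalog,
                                     read_experiments,
                                     striatal_compression_ratio,
                                     total_target_neurons, write_experiments)


@pytest.fixture
def toy_catalog():
    return RegionCatalog(pd.DataFrame({
        "region_id": ["A", "B", "C"],
        "region_name": ["alpha", "beta", "gamma"],
        "neuron_count": [1000, 250, 4000],
    }))


def make_experiment(densities, volume=0.2, proportion=0.95, eid="e1"):
    return TracerExperiment(eid, volume, proportion, pd.Series(densities))


class TestFiltering:
    def test_zero_threshold_retains_whole_catalogue(self, toy_catalog):
        exp = make_experiment({"A": 0.01, "B": 0.002, "C": 0.3})
        retained = filter_targets(exp, toy_catalog, 0.0)
        assert set(retained) == {"A", "B", "C"}
        assert total_target_neurons(retained, toy_catalog) == 5250

    def test_threshold_above_all_densities_empties_list(self, toy_catalog):
        exp = make_experiment({"A": 0.5, "B": 0.9})
        assert filter_targets(exp, toy_catalog, 0.999) == []

    def test_threshold_comparison_is_inclusive(self, toy_catalog):
        exp = make_experiment({"A": 0.10, "B": 0.04, "C": 0.004})
        assert filter_targets(exp, toy_catalog, 0.05) == ["A"]
        # >= comparison: a density exactly at theta is retained
        assert set(filter_targets(exp, toy_catalog, 0.04)) == {"A", "B"}

    def test_regions_outside_catalogue_ignored(self, toy_catalog):
        exp = make_experiment({"A": 0.5, "Z": 0.9})
        assert filter_targets(exp, toy_catalog, 0.0) == ["A"]

    def test_invalid_threshold_rejected(self, toy_catalog):
        exp = make_experiment({"A": 0.5})
        with pytest.raises(ValueError):
            filter_targets(exp, toy_catalog, 1.0)


class TestAggregation:
    def test_empty_and_simple_totals(self, toy_catalog):
        assert total_target_neurons([], toy_catalog) == 0
        assert total_target_neurons(["A", "B"], toy_catalog) == 1250

    def test_unknown_region_raises(self, toy_catalog):
        with pytest.raises(KeyError):
            total_target_neurons(["A", "Z"], toy_catalog)

    def test_column_sum_oracle_on_random_catalogue(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(10, 10_000, size=50)
        catalog = RegionCatalog(pd.DataFrame({
            "region_id": [f"r{i}" for i in range(50)],
            "region_name": [f"region {i}" for i in range(50)],
            "neuron_count": counts,
        }))
        retained = [f"r{i}" for i in range(50)]
        assert total_target_neurons(retained, catalog) == counts.sum()
        dens = pd.Series(rng.uniform(0, 0.999, 50), index=retained)
        oracle = sum(counts[i] * dens.iloc[i] for i in range(50))
        assert arborization_weighted_neurons(retained, dens, catalog) == \
            pytest.approx(oracle)

    def test_weighted_sum_bounds(self, toy_catalog):
        dens = pd.Series({"A": 1.0, "B": 1.0})
        assert arborization_weighted_neurons(["A", "B"], dens, toy_catalog) == 1250
        dens = pd.Series({"A": 0.2})
        assert arborization_weighted_neurons(["A"], dens, toy_catalog) == 200


class TestScalingFit:
    def test_exact_line_recovered(self):
        pts = [(0.1, 6.0), (0.2, 7.0), (0.4, 9.0)]
        fit = fit_scaling_model(pts)
        assert fit.slope == pytest.approx(10.0)
        assert fit.intercept == pytest.approx(5.0)
        mean, lo, hi = fit.predict(0.69)
        assert mean == pytest.approx(11.9)

    def test_duplicated_points_leave_fit_unchanged(self):
        pts = [(0.1, 6.1), (0.2, 7.3), (0.4, 8.8)]
        fit1 = fit_scaling_model(pts)
        fit2 = fit_scaling_model(pts + pts)
        assert fit1.slope == pytest.approx(fit2.slope)
        assert fit1.intercept == pytest.approx(fit2.intercept)

    def test_parameter_recovery_with_noise(self):
        rng = np.random.default_rng(21)
        volumes = np.linspace(0.1, 0.6, 6)
        totals = 2e6 * volumes + 1e5 + rng.normal(0, 2e4, 6)
        fit = fit_scaling_model(list(zip(volumes, totals)))
        se_slope = float(fit._results.bse[1])
        assert abs(fit.slope - 2e6) < 3 * se_slope

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_scaling_model([(0.1, 5.0)])
        with pytest.raises(ValueError):
            fit_scaling_model([(0.1, 5.0), (0.1, 6.0)])

    def test_zero_slope_extrapolation_is_intercept(self):
        fit = fit_scaling_model([(0.1, 42.0), (0.3, 42.0), (0.5, 42.0)])
        mean, _, _ = extrapolate_to_source(fit, SourceNucleusParams())
        assert mean == pytest.approx(42.0)


class TestAsymptoteRule:
    def test_hand_traced_window(self):
        assert detect_asymptote([200, 160, 155, 154.5, 154.2]) == 154.2

    def test_constant_sequence(self):
        assert detect_asymptote([13, 13, 13]) == 13

    def test_steep_sequence_has_no_asymptote(self):
        assert detect_asymptote([300, 250, 200, 150]) is None

    def test_short_sequence_warns_and_returns_none(self):
        with pytest.warns(UserWarning):
            assert detect_asymptote([10, 10]) is None

    def test_returns_final_of_first_window(self):
        # window starts at the first pair of sub-unit changes
        assert detect_asymptote([50, 49.5, 49.2, 40, 39.8, 39.7]) == 49.2


class TestPerExperimentRoute:
    def test_whole_nucleus_injection_uses_all_source_neurons(self, toy_catalog):
        source = SourceNucleusParams(volume=0.69, neuron_count=12_000)
        exp = make_experiment({"A": 0.5}, volume=0.69, proportion=1.0)
        upper, lower = per_experiment_ratio(exp, toy_catalog, source, 0.0)
        # S-hat equals the full source count, so the ratio is total / 12000
        assert upper == pytest.approx(1000 / 12_000)
        assert lower == pytest.approx(500 / 12_000)

    def test_s_hat_arithmetic_from_printed_volumes(self, toy_catalog):
        source = SourceNucleusParams(volume=0.69, neuron_count=12_000)
        exp = make_experiment({"A": 0.5}, volume=0.36, proportion=0.94)
        upper, _ = per_experiment_ratio(exp, toy_catalog, source, 0.0)
        s_hat = 1000 / upper
        assert s_hat == pytest.approx(12_000 * 0.36 * 0.94 / 0.69, rel=1e-9)
        assert s_hat == pytest.approx(5885, abs=1.0)

    def test_raw_volume_flag(self, toy_catalog):
        source = SourceNucleusParams(volume=0.69, neuron_count=12_000)
        exp = make_experiment({"A": 0.5}, volume=0.36, proportion=0.94)
        upper_raw, _ = per_experiment_ratio(exp, toy_catalog, source, 0.0,
                                            use_raw_volume=True)
        assert 1000 / upper_raw == pytest.approx(12_000 * 0.36 / 0.69)


class TestInjectionTable:
    @pytest.mark.parametrize("volume, proportion, expected", [
        (0.23, 0.95, 0.32),   # confined experiment
        (0.17, 0.96, 0.24),   # confined experiment
        (0.54, 0.29, 0.23),   # spilling experiment
        (0.69, 1.00, 1.00),   # whole-nucleus boundary
    ])
    def test_proportion_of_source_injected(self, volume, proportion, expected):
        assert proportion_of_source_injected(volume, proportion) == expected

    def test_oversized_injection_capped_with_warning(self):
        with pytest.warns(UserWarning):
            assert proportion_of_source_injected(2.0, 1.0, 0.69) == 1.0

    def test_reference_table_well_formed(self):
        assert len(ALLEN_SNR_TABLE) == 6
        confined = ALLEN_SNR_TABLE[ALLEN_SNR_TABLE.proportion_in_source > 0.9]
        assert set(confined.index) == {"100141993", "299895444", "175263063"}

    def test_striatal_compression_is_about_sixteen_to_one(self):
        assert striatal_compression_ratio() >= 16


class TestSweepInvariants:
    def test_monotone_retained_counts_and_bound_ordering(self, small_study):
        config, catalog, experiments, _ = small_study
        sweep = ratio_sweep(experiments, catalog, config.source)
        # retained counts non-increasing in theta, per experiment
        diffs = np.diff(sweep.retained_counts, axis=0)
        assert (diffs <= 0).all()
        # density-weighted bound never exceeds the plain neuron-count bound
        assert (sweep.lower_ratios <= sweep.upper_ratios + 1e-12).all()

    def test_aggregates_monotone_in_theta(self, small_study):
        config, catalog, experiments, _ = small_study
        exp = experiments[0]
        uppers, lowers = [], []
        for theta in np.arange(0, 0.05, 0.005):
            retained = filter_targets(exp, catalog, theta)
            uppers.append(total_target_neurons(retained, catalog))
            lowers.append(arborization_weighted_neurons(
                retained, exp.densities, catalog))
        assert (np.diff(uppers) <= 0).all()
        assert (np.diff(lowers) <= 1e-9).all()

    def test_weighted_fit_matches_unweighted_for_uniform_proportions(
            self, small_study):
        config, catalog, experiments, _ = small_study
        for e in experiments:
            e.proportion_in_source = 0.95
        plain = ratio_sweep(experiments, catalog, config.source, weighted=False)
        weighted = ratio_sweep(experiments, catalog, config.source, weighted=True)
        assert np.allclose(plain.upper_ratios, weighted.upper_ratios)
        assert np.allclose(plain.lower_ratios, weighted.lower_ratios)


class TestTableIO:
    def test_round_trip_through_delimited_text(self, tmp_path, small_study):
        config, catalog, experiments, _ = small_study
        catalog.to_csv(tmp_path / "catalog.tsv")
        write_experiments(experiments, tmp_path / "exp.tsv", tmp_path / "dens.tsv")
        cat2 = read_catalog(tmp_path / "catalog.tsv")
        exps2 = read_experiments(tmp_path / "exp.tsv", tmp_path / "dens.tsv")
        assert cat2.total_neurons() == catalog.total_neurons()
        assert len(exps2) == len(experiments)
        for e1, e2 in zip(experiments, exps2):
            assert e1.injection_volume == pytest.approx(e2.injection_volume)
            assert np.allclose(e1.densities.values, e2.densities.values)
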