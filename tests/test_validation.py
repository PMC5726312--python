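"""Agreement statistics: RMSE, banded kappa, decomposition, map validation."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import cohen_kappa_score

from wildmaps import (
    SimConfig,
    ValidationError,
    ValidationPlot,
    agreement_counts,
    filter_certain,
    generate_grid_pair,
    generate_realm_partition,
    generate_validation_plots,
    kappa_with_tolerance,
    map_pressure_free,
    normalize_hfp,
    overlay_hfp,
    percent,
    rmse,
    score_agreement,
    build_low_suite,
    validate_low_map,
    validate_wilderness_map,
)
from wildmaps.validation import _discretize

unit_floats = st.floats(min_value=0.0, max_value=1.0)


def _plot(i, row, col, visual, certain=True):
    return ValidationPlot(i, row, col, visual, certain)


class TestNormalize:
    def test_scale_endpoints_and_midpoint(self):
        assert normalize_hfp(0) == 0.0
        assert normalize_hfp(50) == 1.0
        assert normalize_hfp(25) == 0.5

    def test_uniform_step_over_full_scale(self):
        vals = normalize_hfp(np.arange(51))
        assert np.allclose(np.diff(vals), 0.02)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            normalize_hfp(51)


class TestFilterCertain:
    def test_identity_and_empty_extremes(self):
        certain = [_plot(i, 0, 0, 0.5) for i in range(4)]
        uncertain = [_plot(i, 0, 0, 0.5, certain=False) for i in range(4)]
        assert filter_certain(certain) == certain
        assert filter_certain(uncertain) == []

    def test_mixed_list_preserves_order(self):
        plots = [_plot(i, 0, 0, 0.1, certain=(i % 5 != 0)) for i in range(10)]
        kept = filter_certain(plots)
        assert len(kept) == sum(1 for p in plots if p.certain) == 8
        assert [p.plot_id for p in kept] == [p.plot_id for p in plots if p.certain]


class TestRmse:
    def test_identical_vectors_give_zero(self):
        assert rmse([0.1, 0.5, 0.9], [0.1, 0.5, 0.9]) == 0.0

    def test_constant_offset(self):
        assert rmse([0.0, 0.0], [0.1, 0.1]) == pytest.approx(0.1)

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(100), rng.random(100)
        naive = (sum((x - y) ** 2 for x, y in zip(a, b)) / 100) ** 0.5
        assert rmse(a, b) == pytest.approx(naive, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(unit_floats, min_size=1, max_size=30))
    def test_symmetric_and_zero_iff_equal(self, a):
        b = list(reversed(a))
        assert rmse(a, b) == pytest.approx(rmse(b, a))
        assert rmse(a, a) == 0.0

    def test_rejects_mismatch_and_empty(self):
        with pytest.raises(ValidationError):
            rmse([0.1], [0.1, 0.2])
        with pytest.raises(ValidationError):
            rmse([], [])


class TestKappa:
    def test_perfect_agreement_is_one(self):
        a = [0.1, 0.3, 0.5, 0.9, 0.1]
        assert kappa_with_tolerance(a, a) == pytest.approx(1.0)

    def test_hand_evaluated_two_class_table(self):
        # 2x2 contingency (20,5;5,20): p_o=0.8, p_e=0.5 -> kappa = 0.6
        a = [0.25] * 25 + [0.75] * 25
        b = [0.25] * 20 + [0.75] * 5 + [0.25] * 5 + [0.75] * 20
        assert kappa_with_tolerance(a, b, tolerance=0.5) == pytest.approx(0.6)

    def test_degenerate_single_class_is_undefined(self):
        assert kappa_with_tolerance([0.05] * 10, [0.08] * 10) is None

    @pytest.mark.parametrize("tolerance", [0.15, 0.2, 0.25])
    def test_matches_sklearn_oracle(self, tolerance):
        rng = np.random.default_rng(3)
        a = rng.random(400)
        b = np.clip(a + rng.normal(0, 0.15, 400), 0, 1)
        ours = kappa_with_tolerance(a, b, tolerance)
        ref = cohen_kappa_score(_discretize(a, tolerance), _discretize(b, tolerance))
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_kappa_bounded_by_observed_agreement(self):
        rng = np.random.default_rng(4)
        a, b = rng.random(300), rng.random(300)
        k = kappa_with_tolerance(a, b, 0.2)
        p_o = np.mean(_discretize(a, 0.2) == _discretize(b, 0.2))
        assert k <= p_o + 1e-12

    def test_permuted_labels_average_near_zero(self):
        # chance correction: kappa over label permutations centres on 0
        rng = np.random.default_rng(11)
        a = rng.random(300)
        b = np.clip(a + rng.normal(0, 0.1, 300), 0, 1)
        kappas = []
        for _ in range(1000):
            kappas.append(kappa_with_tolerance(a, rng.permutation(b), 0.2))
        assert abs(float(np.mean(kappas))) < 0.02

    def test_invalid_tolerance_rejected(self):
        with pytest.raises(ValidationError):
            kappa_with_tolerance([0.1], [0.1], tolerance=0.0)


class TestAgreementCounts:
    def test_identical_vectors_all_within(self):
        assert agreement_counts([0.2, 0.4], [0.2, 0.4]) == (2, 0, 0)

    def test_boundary_is_inclusive(self):
        a = [0.5, 0.5, 0.5]
        assert agreement_counts(a, [0.5, 0.7, 0.3]) == (3, 0, 0)
        assert agreement_counts(a, [0.5, 0.71, 0.29]) == (1, 1, 1)

    def test_tolerance_one_puts_everything_within(self):
        rng = np.random.default_rng(5)
        a, b = rng.random(50), rng.random(50)
        assert agreement_counts(a, b, tolerance=1.0) == (50, 0, 0)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.tuples(unit_floats, unit_floats), min_size=1, max_size=50),
        st.floats(min_value=0.01, max_value=1.0),
    )
    def test_decomposition_sums_to_n(self, pairs, tol):
        a, b = zip(*pairs)
        w, above, below = agreement_counts(list(a), list(b), tol)
        assert w + above + below == len(pairs)
        assert min(w, above, below) >= 0


class TestPercent:
    @pytest.mark.parametrize(
        "num,den,expected",
        [(2757, 3114, 88.5), (550, 624, 88.1), (617, 624, 98.9),
         (597, 687, 86.9), (678, 687, 98.7), (0, 10, 0.0)],
    )
    def test_printed_percentages(self, num, den, expected):
        assert percent(num, den) == expected

    def test_half_up_rounding(self):
        assert percent(1, 16) == 6.3   # 6.25 rounds up, not to even
        assert percent(1, 16, decimals=2) == 6.25

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            percent(1, 0)
        with pytest.raises(ValidationError):
            percent(5, 4)


class TestScoreAgreement:
    @pytest.fixture
    def system(self):
        cfg = SimConfig(grid_shape=(48, 48), zero_fraction=0.3,
                        plot_noise_sd=0.05, certain_fraction=0.9, seed=13)
        g93, g09 = generate_grid_pair(cfg)
        plots = generate_validation_plots(g09, cfg, 400)
        return cfg, g93, g09, plots

    def test_report_consistency(self, system):
        _, _, g09, plots = system
        report = score_agreement(overlay_hfp(filter_certain(plots), g09))
        assert report.n_within + report.n_hfp_above + report.n_hfp_below == report.n
        assert report.pct_within == percent(report.n_within, report.n)
        assert set(report.kappa_alt) == {0.15, 0.25}

    def test_noise_free_plots_agree_perfectly(self, system):
        cfg, _, g09, _ = system
        quiet = dataclasses.replace(cfg, plot_noise_sd=0.0)
        plots = overlay_hfp(generate_validation_plots(g09, quiet, 300), g09)
        report = score_agreement(plots)
        assert report.rmse == 0.0
        assert report.kappa == pytest.approx(1.0)
        assert report.pct_within == 100.0

    def test_requires_overlaid_scores(self):
        with pytest.raises(ValidationError):
            score_agreement([_plot(1, 0, 0, 0.5)])


class TestMapValidation:
    @pytest.fixture
    def wilderness_system(self):
        cfg = SimConfig(grid_shape=(48, 48), zero_fraction=0.4,
                        plot_noise_sd=0.0, certain_fraction=1.0, seed=17)
        g93, g09 = generate_grid_pair(cfg)
        wmap = map_pressure_free(g09, min_area_km2=10.0)
        plots = generate_validation_plots(g09, cfg, 400)
        return g09, wmap, plots

    def test_noise_free_wilderness_plots_are_pressure_free(self, wilderness_system):
        _, wmap, plots = wilderness_system
        report = validate_wilderness_map(wmap, plots)
        assert report.n > 0
        assert report.pct_agree == 100.0
        assert report.pct_within_tolerance == 100.0

    def test_counts_on_hand_built_map(self):
        g = np.zeros((20, 20), dtype=np.int16)
        from wildmaps import PressureGrid
        wmap = map_pressure_free(PressureGrid(g, epoch="2009"), min_area_km2=10.0)
        plots = [
            _plot(1, 0, 0, 0.0), _plot(2, 1, 1, 0.1),
            _plot(3, 2, 2, 0.3), _plot(4, 3, 3, 0.0),
        ]
        report = validate_wilderness_map(wmap, plots)
        assert (report.n, report.n_agree, report.n_within_tolerance) == (4, 2, 3)
        assert report.pct_agree == 50.0

    def test_empty_intersection_yields_zero_report(self):
        from wildmaps import PressureGrid
        g = np.ones((15, 15), dtype=np.int16)
        wmap = map_pressure_free(PressureGrid(g), min_area_km2=10.0)
        report = validate_wilderness_map(wmap, [_plot(1, 0, 0, 0.0)])
        assert report.n == 0

    def test_noise_free_low_plots_below_threshold(self):
        cfg = SimConfig(grid_shape=(48, 48), n_realms=3, zero_fraction=0.1,
                        plot_noise_sd=0.0, certain_fraction=1.0, seed=19)
        g93, g09 = generate_grid_pair(cfg)
        realms = generate_realm_partition(cfg, grid=g93)
        suite = build_low_suite(g93, g09, realms, min_area_km2=10.0)
        plots = generate_validation_plots(g09, cfg, 400)
        report = validate_low_map(suite.low_2009_current, plots)
        assert report.n > 0
        assert report.pct_agree == 100.0

    def test_max_thresholds_admit_every_plot(self):
        from wildmaps import ThresholdEntry, ThresholdTable

        cfg = SimConfig(grid_shape=(32, 32), n_realms=2, zero_fraction=0.2,
                        plot_noise_sd=0.2, seed=23)
        g93, g09 = generate_grid_pair(cfg)
        realms = generate_realm_partition(cfg, grid=g93)
        suite = build_low_suite(g93, g09, realms, min_area_km2=10.0)
        maxed = ThresholdTable(
            "2009", 0.10,
            {rid: ThresholdEntry(50, e.realm_area_km2, e.realm_area_km2)
             for rid, e in suite.thresholds_2009.entries.items()},
        )
        low = dataclasses.replace(suite.low_2009_current, thresholds=maxed)
        plots = generate_validation_plots(g09, cfg, 200)
        report = validate_low_map(low, plots)
        if report.n:
            assert report.pct_agree == 100.0

    def test_missing_realm_threshold_rejected(self):
        from wildmaps import ThresholdTable

        cfg = SimConfig(grid_shape=(32, 32), n_realms=2, zero_fraction=0.3,
                        plot_noise_sd=0.0, seed=29)
        g93, g09 = generate_grid_pair(cfg)
        realms = generate_realm_partition(cfg, grid=g93)
        suite = build_low_suite(g93, g09, realms, min_area_km2=10.0)
        empty = ThresholdTable("2009", 0.10, {})
        low = dataclasses.replace(suite.low_2009_current, thresholds=empty)
        plots = generate_validation_plots(g09, cfg, 200)
        if validate_low_map(suite.low_2009_current, plots).n:
            with pytest.raises(ValidationError):
                validate_low_map(low, plots)
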