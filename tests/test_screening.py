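"""The four-stage screening cascade and its statistical primitives."""

import numpy as np
import pytest
from scipy import stats as sps

from metabroscreen import screening
from metabroscreen.screening import (
    GaussianFit,
    ScreeningConfig,
    auc,
    detection_filter,
    fit_gaussian_log_ratios,
    fold_change,
    fold_filter,
    rank_sum_test,
    run_screening,
)
from metabroscreen.synthetic_data import GeneratorConfig, generate_cohort

from conftest import make_matrix, make_samples


class TestDetectionFilter:
    def test_kept_and_removed_around_the_half_boundary(self):
        # 105 training samples: 71 detections kept (71 > 52.5); 52 removed
        x = np.zeros((105, 2))
        x[:71, 0] = 5.0
        x[:52, 1] = 5.0
        matrix = make_matrix(x)
        samples = make_samples(55, 50)
        kept = detection_filter(matrix, samples)
        assert kept.tolist() == [0]

    def test_even_training_size_strict_majority(self):
        # 4 samples: 2 detections is not >2, 3 is
        x = np.zeros((4, 2))
        x[:2, 0] = 1.0
        x[:3, 1] = 1.0
        kept = detection_filter(make_matrix(x), make_samples(2, 2))
        assert kept.tolist() == [1]

    def test_matches_brute_force_recount(self, rng):
        x = rng.lognormal(size=(30, 40))
        x[rng.random(x.shape) < 0.5] = 0.0
        matrix = make_matrix(x)
        samples = make_samples(16, 14)
        kept = detection_filter(matrix, samples)
        expected = [
            j for j in range(40)
            if sum(1 for i in range(30) if x[i, j] > 0) > 15
        ]
        assert kept.tolist() == expected

    def test_empty_train_split_raises(self):
        matrix = make_matrix(np.ones((2, 2)))
        samples = make_samples(0, 0, n_case_test=1, n_control_test=1)
        with pytest.raises(RuntimeError):
            detection_filter(matrix, samples)


class TestFoldChange:
    def test_exact_doubling(self):
        control = np.tile([1.0, 3.0, 5.0], (4, 1))
        case = 2 * control
        matrix = make_matrix(np.vstack([case, control]))
        ratio, log_ratio = fold_change(matrix, make_samples(4, 4))
        np.testing.assert_allclose(ratio, 2.0)
        np.testing.assert_allclose(log_ratio, np.log10(2.0))

    def test_identical_groups_give_unit_ratio(self):
        block = np.tile([2.0, 7.0], (3, 1))
        matrix = make_matrix(np.vstack([block, block]))
        ratio, log_ratio = fold_change(matrix, make_samples(3, 3))
        np.testing.assert_allclose(ratio, 1.0)
        np.testing.assert_allclose(log_ratio, 0.0)

    def test_zero_control_mean_is_nan_and_logged(self, caplog):
        x = np.array([[1.0], [1.0], [0.0], [0.0]])
        matrix = make_matrix(x)
        with caplog.at_level("WARNING"):
            ratio, log_ratio = fold_change(matrix, make_samples(2, 2))
        assert np.isnan(ratio[0]) and np.isnan(log_ratio[0])
        assert "zero control mean" in caplog.text

    def test_planted_tenfold_marker_within_three_se(self):
        cfg = GeneratorConfig(
            n_case=55, n_control=50, n_case_test=0, n_control_test=0,
            n_ions=10, n_markers=1, marker_fold_range=(10.0, 10.0),
            dropout_prob_range=(0.0, 0.0), marker_dropout_prob=0.0,
            base_log10_sd_range=(0.2, 0.2), seed=21,
        )
        matrix, samples, truth = generate_cohort(cfg)
        ratio, _ = fold_change(matrix, samples)
        assert 8.0 <= ratio[truth.marker_ion_indices[0]] <= 12.5


class TestGaussianFit:
    def test_noiseless_curve_recovered_to_six_decimals(self):
        # counts generated exactly from the model leave zero residual
        centers = np.linspace(-2, 3, 50)
        counts = 100.0 * np.exp(-((centers - 0.2) ** 2) / (2 * 0.5**2))
        fit = screening.fit_gaussian_curve(centers, counts, p0=(80.0, 0.0, 1.0))
        np.testing.assert_allclose(fit, [100.0, 0.2, 0.5], atol=1e-6)

    def test_monte_carlo_recovery(self, rng):
        draws = rng.normal(0.0, 0.5, size=100_000)
        fit = fit_gaussian_log_ratios(draws, bins=60)
        assert not fit.fallback
        assert -0.02 <= fit.mean <= 0.02
        assert 0.48 <= fit.sd <= 0.52

    def test_degenerate_input_falls_back_with_warning(self):
        with pytest.warns(RuntimeWarning):
            fit = fit_gaussian_log_ratios(np.zeros(10), bins=20)
        assert fit.fallback

    def test_requires_ten_finite_values(self):
        with pytest.raises(ValueError):
            fit_gaussian_log_ratios(np.array([1.0, 2.0, np.nan]), bins=10)


class TestFoldFilter:
    def test_boundary_at_one_sd(self):
        cfg = ScreeningConfig()
        fit = GaussianFit(amplitude=1.0, mean=0.0, sd=0.3)
        mask = fold_filter(np.array([0.31, 0.29]), fit, cfg)
        assert mask.tolist() == [True, False]

    def test_negative_log_ratio_never_kept(self):
        cfg = ScreeningConfig()
        fit = GaussianFit(amplitude=1.0, mean=-0.5, sd=0.2)
        # -0.1 is 2 SD above the mean but down-regulated ions are excluded
        assert fold_filter(np.array([-0.1]), fit, cfg).tolist() == [False]

    def test_kept_fraction_matches_gaussian_tail(self, rng):
        mu, sd, n = 0.05, 0.3, 200_000
        lr = rng.normal(mu, sd, size=n)
        cfg = ScreeningConfig()
        fit = GaussianFit(amplitude=1.0, mean=mu, sd=sd)
        frac = fold_filter(lr, fit, cfg).mean()
        expected = 1.0 - sps.norm.cdf(1.0)  # mu+sd > 0, positivity not binding
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * se


class TestRankSum:
    def test_exact_small_sample(self):
        # all 20 rank assignments enumerable; most extreme two give p = 0.1
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        assert rank_sum_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestAuc:
    def test_perfect_separation(self):
        assert auc([4, 5, 6], [1, 2, 3]) == 1.0
        assert auc([1, 2, 3], [4, 5, 6]) == 0.0

    def test_all_ties_give_half(self):
        assert auc([2.0, 2.0], [2.0, 2.0, 2.0]) == 0.5

    def test_complement_identity(self, rng):
        for _ in range(20):
            x = rng.normal(size=8)
            y = rng.normal(size=5)
            assert auc(x, y) + auc(y, x) == pytest.approx(1.0)

    def test_u_statistic_link_on_tie_free_data(self, rng):
        for _ in range(20):
            x = rng.normal(size=12)
            y = rng.normal(size=9)
            u = sps.mannwhitneyu(x, y, alternative="two-sided").statistic
            assert auc(x, y) == pytest.approx(u / (12 * 9))


class TestRunScreening:
    def test_stage_monotonicity(self, small_cohort):
        matrix, samples, _ = small_cohort
        res = run_screening(matrix, samples)
        stages = np.array([s.passed_stage for s in res.stats])
        assert np.all(stages >= 1)
        # survivors of stage k also satisfy every earlier threshold
        for s in res.stats:
            if s.passed_stage >= 3:
                assert s.p_value < 0.05
            if s.passed_stage >= 4:
                assert s.auc >= 0.7

    def test_impossible_auc_threshold_gives_no_candidates(self, small_cohort):
        matrix, samples, _ = small_cohort
        res = run_screening(matrix, samples, ScreeningConfig(auc_min=1.01))
        assert res.candidates == []

    def test_candidates_sorted_by_ascending_p(self, small_cohort):
        matrix, samples, _ = small_cohort
        res = run_screening(matrix, samples)
        ps = [s.p_value for s in res.candidates]
        assert ps == sorted(ps)

    def test_invariant_under_sample_and_ion_reordering(self, rng, small_cohort):
        matrix, samples, _ = small_cohort
        res = run_screening(matrix, samples)
        perm_s = rng.permutation(matrix.n_samples)
        perm_i = rng.permutation(matrix.n_ions)
        shuffled = matrix.subset_samples([matrix.samples[i] for i in perm_s])
        shuffled = shuffled.subset_ions(perm_i.tolist())
        res2 = run_screening(shuffled, samples)
        by_ion = {s.ion.label: s for s in res.stats}
        by_ion2 = {s.ion.label: s for s in res2.stats}
        assert set(by_ion) == set(by_ion2)
        for label, s in by_ion.items():
            s2 = by_ion2[label]
            assert s.passed_stage == s2.passed_stage
            assert s.p_value == pytest.approx(s2.p_value)
            assert s.auc == pytest.approx(s2.auc)

    def test_ionstats_round_trip(self, tmp_path, small_cohort):
        matrix, samples, _ = small_cohort
        res = run_screening(matrix, samples)
        screening.write_ionstats(res, tmp_path / "ionstats.tsv")
        df = screening.read_ionstats(tmp_path / "ionstats.tsv")
        assert list(df.columns) == [
            "ion", "n_detect_case", "n_detect_control", "ratio", "log_ratio",
            "p_value", "auc", "passed_stage",
        ]
        assert len(df) == len(res.stats)
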