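"""Fold construction, cross-validation and the ageing-precision metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import gaussian_kde, norm

from otoage.evaluation import (PredictionSet, compute_metrics, cv_single,
                               default_grid, kde, kl_between_samples,
                               kl_divergence, make_fold_plan, mean_cv,
                               off_percentage, residual_sd_by_age, rmse,
                               run_cross_validation, shared_grid,
                               stratified_split)
from otoage.model import ModelConfig
from otoage.pipeline import DatasetTable


def metadata_table(ages, sexes, ids=None):
    n = len(ages)
    ids = ids if ids is not None else [f"s{i}" for i in range(n)]
    return DatasetTable(np.array(ids, dtype=object),
                        np.array(ages, dtype=float),
                        np.array(sexes, dtype=object),
                        np.full(n, np.nan))


@pytest.fixture(scope="module")
def full_scale_table():
    """3,540 known-sex rows plus 703 unknowns: the study's composition."""
    rng = np.random.default_rng(0)
    ages = list(rng.integers(1, 27, size=3540)) + list(rng.integers(1, 27, 703))
    sexes = (["male"] * 1465 + ["female"] * 2075 + ["unknown"] * 703)
    return metadata_table(ages, sexes)


class TestStratifiedSplit:
    def test_full_scale_folds_are_exactly_equal(self, full_scale_table):
        asg = stratified_split(full_scale_table, k=10, seed=1)
        sizes = [len(asg.fold_ids(f)) for f in range(1, 11)]
        assert sizes == [354] * 10

    def test_one_row_per_fold(self):
        t = metadata_table(range(1, 11), ["male"] * 10)
        asg = stratified_split(t, k=10, seed=0)
        assert sorted(len(asg.fold_ids(f)) for f in range(1, 11)) == [1] * 10

    def test_stratum_dealt_evenly(self):
        t = metadata_table([5] * 20, ["female"] * 20)
        asg = stratified_split(t, k=10, seed=0)
        assert [len(asg.fold_ids(f)) for f in range(1, 11)] == [2] * 10

    def test_per_age_counts_balanced(self, full_scale_table):
        asg = stratified_split(full_scale_table, k=10, seed=2)
        known = full_scale_table.known_sex_mask
        ages = full_scale_table.read_ages[known].astype(int)
        ids_to_age = dict(zip(full_scale_table.sample_ids[known], ages))
        for age in np.unique(ages):
            counts = [sum(1 for sid in asg.fold_ids(f)
                          if ids_to_age[sid] == age) for f in range(1, 11)]
            assert max(counts) - min(counts) <= 1

    def test_unknowns_not_folded(self, full_scale_table):
        asg = stratified_split(full_scale_table, k=10, seed=1)
        assert len(asg.unknown_ids) == 703
        assert set(asg.unknown_ids).isdisjoint(asg.known_ids)

    def test_k_too_large_rejected(self):
        t = metadata_table([1, 2, 3], ["male"] * 3)
        with pytest.raises(ValueError, match="exceeds"):
            stratified_split(t, k=5)

    def test_k_below_two_rejected(self, full_scale_table):
        with pytest.raises(ValueError):
            stratified_split(full_scale_table, k=1)


@pytest.fixture(scope="module")
def plan(full_scale_table):
    asg = stratified_split(full_scale_table, k=10, seed=1)
    return asg, make_fold_plan(asg)


class TestFoldPlan:

    def test_trial_three_layout(self, plan):
        asg, p = plan
        t3 = p.trials[2]
        assert t3.index == 3
        assert set(t3.test_ids) == set(asg.fold_ids(3))
        assert set(t3.val_ids) == set(asg.fold_ids(4))
        expected_train = set().union(
            *[set(asg.fold_ids(f)) for f in (1, 2, 5, 6, 7, 8, 9, 10)],
            set(asg.unknown_ids))
        assert set(t3.train_ids) == expected_train

    def test_last_trial_wraps_validation_to_first_fold(self, plan):
        asg, p = plan
        t10 = p.trials[9]
        assert set(t10.val_ids) == set(asg.fold_ids(1))

    def test_every_known_sample_tested_exactly_once(self, plan):
        asg, p = plan
        tested = [sid for t in p.trials for sid in t.test_ids]
        assert len(tested) == len(asg.known_ids)
        assert set(tested) == set(asg.known_ids)

    def test_unknowns_only_in_training(self, plan):
        asg, p = plan
        unknown = set(asg.unknown_ids)
        for t in p.trials:
            assert unknown.isdisjoint(t.test_ids)
            assert unknown.isdisjoint(t.val_ids)
            assert unknown <= set(t.train_ids)

    def test_test_val_disjoint_within_trial(self, plan):
        _, p = plan
        for t in p.trials:
            assert set(t.test_ids).isdisjoint(t.val_ids)
            assert set(t.test_ids).isdisjoint(t.train_ids)


@pytest.fixture(scope="module")
def cv_result(small_table):
    asg = stratified_split(small_table, k=3, seed=0)
    cv_plan = make_fold_plan(asg)
    cfg = ModelConfig(input_side=32, dropout_rate=0.0, learning_rate=1e-3)
    return asg, cv_plan, run_cross_validation(cv_plan, small_table, cfg,
                                              seed=0, patience=2, max_epochs=2)


class TestRunCrossValidation:

    def test_coverage_and_report_count(self, cv_result, small_table):
        asg, plan, (pred_set, reports) = cv_result
        assert len(reports) == 3
        assert len(pred_set) == int(small_table.known_sex_mask.sum())
        assert set(pred_set.frame["sample_id"]) == set(asg.known_ids)

    def test_unknowns_never_tested(self, cv_result):
        asg, _, (pred_set, _) = cv_result
        assert set(pred_set.frame["sample_id"]).isdisjoint(asg.unknown_ids)

    def test_rmse_varies_across_trials(self, cv_result):
        _, _, (_, reports) = cv_result
        rmses = [r.rmse for r in reports]
        assert np.std(rmses) > 0

    def test_deterministic_rerun(self, cv_result, small_table):
        _, plan, (pred_set, _) = cv_result
        cfg = ModelConfig(input_side=32, dropout_rate=0.0, learning_rate=1e-3)
        pred2, _ = run_cross_validation(plan, small_table, cfg, seed=0,
                                        patience=2, max_epochs=2)
        pd.testing.assert_frame_equal(pred_set.frame, pred2.frame)


class TestPointMetrics:
    def test_rmse_hand_cases(self):
        assert rmse(([2, 4], [1, 2])) == pytest.approx(np.sqrt(2.5))
        assert rmse(([10], [7])) == 3.0
        assert rmse(([5, 5], [5, 5])) == 0.0

    def test_cv_single_hand_case(self):
        assert cv_single(10, 12) == pytest.approx(np.sqrt(2) / 11, abs=1e-12)
        assert cv_single(10, 10) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(y=st.floats(0.5, 30), yhat=st.floats(0.5, 30))
    def test_cv_single_equals_scaled_absolute_difference(self, y, yhat):
        """The two-reading CV equals |dy| / (sqrt(2) * mean age)."""
        ybar = (y + yhat) / 2
        assert cv_single(y, yhat) == pytest.approx(
            abs(yhat - y) / (np.sqrt(2) * ybar), abs=1e-12)

    def test_cv_single_symmetric(self):
        assert cv_single(10, 12) == cv_single(12, 10)

    def test_cv_single_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            cv_single(0.0, 0.0)

    def test_mean_cv_is_mean(self):
        ps = (np.array([10.0, 10.0]), np.array([10.0, 12.0]))
        assert mean_cv(ps) == pytest.approx(cv_single(10, 12) / 2)

    def test_mean_cv_scale_invariant(self):
        y = np.array([4.0, 9.0, 14.0])
        yhat = np.array([5.0, 8.0, 15.5])
        assert mean_cv((y, yhat)) == pytest.approx(mean_cv((3 * y, 3 * yhat)))

    def test_off_percentage_rounding(self):
        assert off_percentage(([10.0], [10.4]), 0) == 100.0
        assert off_percentage(([10.0], [11.6]), 0) == 0.0
        assert off_percentage(([10.0], [11.6]), 1) == 0.0  # rounds to 12
        assert off_percentage(([10.0], [10.5]), 0) == 0.0  # half away: 11
        assert off_percentage(([10.0], [10.5]), 1) == 100.0

    def test_off_percentage_perfect(self):
        ps = (np.arange(1.0, 11.0), np.arange(1.0, 11.0))
        assert off_percentage(ps, 0) == 100.0
        assert off_percentage(ps, 1) == 100.0


class TestResidualSdByAge:
    def _pred_set(self, ages, preds):
        return PredictionSet.from_arrays(
            [f"s{i}" for i in range(len(ages))], ages, preds,
            ["male"] * len(ages))

    def test_zero_residuals(self):
        ps = self._pred_set([3, 3, 7, 7], [3, 3, 7, 7])
        out = residual_sd_by_age(ps)
        assert set(out.index) == {3, 7}
        assert (out == 0).all()

    def test_hand_case(self):
        ps = self._pred_set([10, 10], [11, 9])
        assert residual_sd_by_age(ps)[10] == pytest.approx(np.sqrt(2))

    def test_singleton_age_omitted(self):
        ps = self._pred_set([4, 4, 9], [4, 5, 9])
        assert 9 not in residual_sd_by_age(ps).index


class TestKdeAndKl:
    def test_kde_integrates_to_one(self, rng):
        est = kde(rng.normal(5, 2, size=2000))
        assert abs(est.integral() - 1.0) < 1e-3

    def test_kde_symmetric_sample(self):
        samples = np.concatenate([np.linspace(-3, 3, 100)])
        est = kde(samples)
        d = est.density
        np.testing.assert_allclose(d, d[::-1], atol=1e-10)

    def test_kde_consistent_with_true_pdf(self):
        """At n = 1e5 the Silverman KDE's bias (O(bw^2) ~ 2e-3) plus noise
        (~5e-3 at the mode) keeps the estimate within 0.01 of the true pdf."""
        rng = np.random.default_rng(4)
        samples = rng.normal(0, 1, size=100_000)
        est = kde(samples)
        assert np.max(np.abs(est.density - norm.pdf(est.grid))) < 0.01

    def test_kde_close_to_scipy_gaussian_kde(self):
        """Independent KDE route: scipy's estimator with its Silverman rule."""
        rng = np.random.default_rng(8)
        samples = rng.normal(10, 3, size=5000)
        grid = default_grid(samples)
        ours = kde(samples, grid).density
        theirs = gaussian_kde(samples, bw_method="silverman")(grid)
        assert np.max(np.abs(ours - theirs)) < 0.01

    def test_kl_identity_zero(self, rng):
        samples = rng.normal(0, 1, size=500)
        grid = default_grid(samples)
        p = kde(samples, grid)
        assert abs(kl_divergence(p, p)) <= 1e-9

    def test_kl_nonnegative(self, rng):
        a = rng.normal(0, 1, 400)
        b = rng.normal(0.3, 1.4, 400)
        assert kl_between_samples(a, b) >= -1e-9
        assert kl_between_samples(b, a) >= -1e-9

    def test_kl_mismatched_grids_rejected(self, rng):
        a = kde(rng.normal(0, 1, 100), np.linspace(-5, 5, 64))
        b = kde(rng.normal(0, 1, 100), np.linspace(-4, 6, 64))
        with pytest.raises(ValueError, match="grid"):
            kl_divergence(a, b)

    def test_kl_between_shifted_normals_matches_closed_form(self):
        """KL(N(0,1) || N(1,1)) = 1/2; KDE + quadrature should land nearby."""
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 20_000)
        b = rng.normal(1, 1, 20_000)
        assert kl_between_samples(a, b) == pytest.approx(0.5, abs=0.06)

    def test_configured_sex_age_distributions_diverge(self, metadata_population):
        ages = {s: [] for s in ("male", "female")}
        for r in metadata_population:
            if r.sex in ages:
                ages[r.sex].append(float(r.read_age))
        assert kl_between_samples(ages["female"], ages["male"]) > 0.01


class TestComputeMetrics:
    def test_report_invariants(self, rng):
        n = 200
        y = rng.integers(1, 20, n).astype(float)
        yhat = np.maximum(y + rng.normal(0, 1.5, n), 0.1)
        sex = np.where(rng.random(n) < 0.5, "male", "female").astype(object)
        ps = PredictionSet.from_arrays([f"s{i}" for i in range(n)], y, yhat, sex)
        rep = compute_metrics(ps)
        assert rep.off0_pct <= rep.off1_pct
        assert rep.rmse >= 0 and rep.mean_cv >= 0
        assert set(rep.kl_by_sex) == {"male", "female"}
        assert rep.n == n

    def test_negative_prediction_rejected(self):
        with pytest.raises(ValueError):
            PredictionSet.from_arrays(["a"], [5.0], [-0.1], ["male"])
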