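"""R² scoring, benchmark experiments and the statistical machinery."""

import numpy as np
import pytest
from scipy import stats

from neuroar.errors import AlignmentError, InvalidConfigError, UndefinedScoreError
from neuroar.evaluation import (bh_fdr, data_scaling, evaluate_model,
                                group_vs_individual, r2_score,
                                subject_specificity, wilcoxon_paired)
from neuroar.models import ModelConfig, build_model, fit
from neuroar.preprocess import make_windows, zscore_per_run

from conftest import make_series


class TestR2Score:
    def test_perfect_and_mean_predictions(self, rng):
        y = rng.standard_normal((20, 3))
        np.testing.assert_allclose(r2_score(y, y), 1.0)
        np.testing.assert_allclose(r2_score(y, np.tile(y.mean(axis=0), (20, 1))), 0.0,
                                   atol=1e-12)

    def test_worked_example(self):
        y = np.array([[0.0], [1], [2], [3]])
        yhat = np.array([[0.0], [0], [2], [2]])
        assert r2_score(y, yhat)[0] == pytest.approx(0.6)

    def test_can_be_negative(self, rng):
        y = rng.standard_normal((30, 1))
        assert r2_score(y, -5 * y)[0] < 0

    def test_zero_variance_target_rejected(self):
        with pytest.raises(UndefinedScoreError):
            r2_score(np.ones((10, 1)), np.zeros((10, 1)))


class TestEvaluateModel:
    def _oracle_model(self, couplings):
        P = couplings.shape[1]
        m = build_model(ModelConfig("linear_multi", k=1, bias=False), P)
        m.params["W0"] = couplings[0].T.copy()
        return m

    def test_zero_predictor_scores_near_zero(self, rng):
        ts = zscore_per_run(make_series(rng.standard_normal((500, 3))))
        m = build_model(ModelConfig("linear_multi", k=1, bias=False), 3)
        m.params["W0"] = np.zeros((3, 3))
        recs = evaluate_model(m, [ts], [1])
        assert abs(recs[0].r2_mean) < 0.05

    def test_true_model_hits_noise_ceiling(self, var1_system):
        from neuroar.cohort import simulate_run
        couplings, _ = var1_system
        test = simulate_run(couplings, None, 1.0, 4000, seed=77)
        recs = evaluate_model(self._oracle_model(couplings), [test], [1])
        ceiling = float((1 - 1.0 / test.data.var(axis=0)).mean())
        assert recs[0].r2_mean == pytest.approx(ceiling, abs=0.05)

    def test_one_record_per_run_and_lag(self, var1_system, var1_runs):
        couplings, _ = var1_system
        _, test = var1_runs
        recs = evaluate_model(self._oracle_model(couplings), test, [1, 2, 3])
        assert len(recs) == len(test) * 3

    def test_parcel_mask_restricts_mean(self, var1_system, var1_runs):
        couplings, _ = var1_system
        _, test = var1_runs
        mask = np.zeros(10, dtype=bool)
        mask[:4] = True
        recs = evaluate_model(self._oracle_model(couplings), test[:1], [1], mask=mask)
        assert recs[0].r2_mean == pytest.approx(recs[0].r2_per_parcel[:4].mean())


def _specificity_cohort(divergence, seed):
    from neuroar.cohort import CohortConfig, generate_cohort
    from neuroar.preprocess import split_runs
    cfg = CohortConfig(n_subjects=3, n_parcels=15, n_runs_per_condition={"movie": 11},
                       run_length=300, subject_divergence=divergence, seed=seed)
    runs, _ = generate_cohort(cfg)
    by = {}
    for ts in runs:
        by.setdefault(ts.subject, []).append(zscore_per_run(ts))
    models, test_runs = {}, {}
    for s, rl in by.items():
        rl = sorted(rl, key=lambda t: (t.condition, t.run))
        split = split_runs(rl, 3 / 11)
        m = build_model(ModelConfig("linear_multi", k=1, seed=0), 15)
        models[s] = fit(m, make_windows(list(split.train), 1, 1), epochs=30,
                        batch_size=256, learning_rate=0.02, seed=0)
        test_runs[s] = list(split.val) + list(split.test)
    return models, test_runs


class TestSubjectSpecificity:
    def test_distinct_subjects_positive_differences(self):
        models, test_runs = _specificity_cohort(1.0, 501)
        diffs, tests = subject_specificity(models, test_runs, lags=[1])
        assert diffs["difference"].mean() > 0
        pair_means = diffs.groupby(["model_subject", "other_subject"])["difference"].mean()
        assert (pair_means > 0).all()

    def test_identical_subjects_null(self):
        models, test_runs = _specificity_cohort(0.0, 701)
        diffs, tests = subject_specificity(models, test_runs, lags=[1])
        assert abs(diffs["difference"].mean()) < 0.02
        assert tests["reject"].sum() == 0

    def test_single_subject_rejected(self):
        models, test_runs = _specificity_cohort(0.0, 702)
        one = {"sub-01": models["sub-01"]}
        with pytest.raises(AlignmentError):
            subject_specificity(one, {"sub-01": test_runs["sub-01"]})


class TestGroupVsIndividual:
    def _setup(self, divergence, seed):
        from neuroar.cohort import CohortConfig, generate_cohort
        cfg = CohortConfig(n_subjects=3, n_parcels=12, n_runs_per_condition={"movie": 8},
                           run_length=300, subject_divergence=divergence, seed=seed)
        runs, _ = generate_cohort(cfg)
        by = {}
        for ts in runs:
            by.setdefault(ts.subject, []).append(zscore_per_run(ts))
        train_by, test_by = {}, {}
        for s, rl in by.items():
            rl = sorted(rl, key=lambda t: (t.condition, t.run))
            train_by[s], test_by[s] = rl[:5], rl[5:]
        return train_by, test_by

    def test_distinct_subjects_favor_individual(self):
        train_by, test_by = self._setup(1.0, 811)
        tab = group_vs_individual(train_by, test_by, ModelConfig("linear_multi", k=1),
                                  4, lags=[1], seed=0, epochs=30, batch_size=256,
                                  learning_rate=0.02)
        assert tab["difference"].mean() > 0

    def test_identical_subjects_no_gap(self):
        train_by, test_by = self._setup(0.0, 911)
        tab = group_vs_individual(train_by, test_by, ModelConfig("linear_multi", k=1),
                                  4, lags=[1], seed=0, epochs=30, batch_size=256,
                                  learning_rate=0.02)
        assert abs(tab["difference"].mean()) < 0.02

    def test_insufficient_runs_rejected(self):
        train_by, test_by = self._setup(0.0, 912)
        with pytest.raises(InvalidConfigError):
            group_vs_individual(train_by, test_by, ModelConfig("linear_multi", k=1),
                                99, lags=[1], epochs=2)


class TestDataScaling:
    def test_identical_seed_rows_and_learning_curve(self, var1_system):
        from neuroar.cohort import simulate_run
        couplings, _ = var1_system
        train = [zscore_per_run(simulate_run(couplings, None, 1.0, 300, seed=20 + r,
                                             run=f"run-{r:02d}"))
                 for r in range(6)]
        val = [zscore_per_run(simulate_run(couplings, None, 1.0, 300, seed=50,
                                           run="run-v"))]
        cfg = ModelConfig("linear_multi", k=1, seed=0)
        a = data_scaling(train, val, cfg, [1, 6], repetitions=2, seed=3, epochs=20,
                         batch_size=256, learning_rate=0.02)
        b = data_scaling(train, val, cfg, [1, 6], repetitions=2, seed=3, epochs=20,
                         batch_size=256, learning_rate=0.02)
        assert a.equals(b)
        means = a.groupby("run_count")["r2_mean"].mean()
        assert means[6] > means[1]

    def test_too_large_count_rejected(self, var1_runs):
        train, test = var1_runs
        with pytest.raises(InvalidConfigError):
            data_scaling(train, test, ModelConfig("linear_multi", k=1), [99])


class TestWilcoxon:
    def test_all_positive_distinct_n6(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        assert wilcoxon_paired(x, np.zeros(6)) == pytest.approx(2 / 64)

    def test_identical_samples_degenerate(self):
        x = np.arange(6.0)
        with pytest.warns(UserWarning):
            assert wilcoxon_paired(x, x) == 1.0

    def test_antisymmetric_differences(self):
        d = np.array([1.0, -1, 2, -2, 3, -3])
        assert wilcoxon_paired(d, np.zeros(6)) == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_scipy_exact_without_ties(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.standard_normal(12)
        expected = stats.wilcoxon(d, method="exact", alternative="two-sided").pvalue
        assert wilcoxon_paired(d, np.zeros(12)) == pytest.approx(expected, rel=1e-10)

    def test_large_sample_approximation_close_to_scipy(self):
        rng = np.random.default_rng(9)
        d = rng.standard_normal(60) + 0.3
        ours = wilcoxon_paired(d, np.zeros(60))
        ref = stats.wilcoxon(d, method="approx", correction=False,
                             alternative="two-sided").pvalue
        assert ours == pytest.approx(ref, rel=1e-6)


class TestBhFdr:
    def test_step_up_by_hand(self):
        reject, p_adj = bh_fdr([0.01, 0.04, 0.3], alpha=0.05)
        assert list(reject) == [True, False, False]

    def test_all_ones_none_rejected(self):
        reject, _ = bh_fdr([1.0, 1.0, 1.0])
        assert not reject.any()

    def test_single_pvalue_raw_threshold(self):
        reject, p_adj = bh_fdr([0.04], alpha=0.05)
        assert reject[0] and p_adj[0] == pytest.approx(0.04)

    def test_adjusted_monotone_in_raw(self, rng):
        p = rng.random(20)
        _, p_adj = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(p_adj[order]) >= -1e-12)

    def test_empty_input(self):
        reject, p_adj = bh_fdr([])
        assert reject.size == 0 and p_adj.size == 0


class TestBhProperties:
    from hypothesis import given, settings, strategies as st

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30),
           st.floats(min_value=0.01, max_value=0.2))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_step_up_definition(self, pvals, alpha):
        # oracle: reject all p <= p_(k*) with k* = max{k: p_(k) <= alpha k / m}
        reject, _ = bh_fdr(pvals, alpha)
        p = np.asarray(pvals)
        order = np.sort(p)
        m = p.size
        ks = [k for k in range(1, m + 1) if order[k - 1] <= alpha * k / m]
        if not ks:
            assert not reject.any()
        else:
            thresh = order[max(ks) - 1]
            np.testing.assert_array_equal(reject, p <= thresh)
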