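"""Reference benchmark protocols at desk scale.

Each function runs one headline check end to end — simulate, preprocess,
build graphs, train, evaluate — and returns plain numbers. They are the
package's own regression benchmarks: the problem sizes are chosen so the
full set runs in minutes on one CPU while leaving each effect clearly
resolvable (see docs/methods.md for the rationale behind each size).
"""

from __future__ import annotations

import numpy as np

from .cohort import CohortConfig, generate_cohort, make_coupling, simulate_run
from .dynamics import high_frequency_fraction, power_spectrum
from .evaluation import evaluate_model, subject_specificity
from .graphs import Connectome, random_connectome, scaled_laplacian
from .models import (ModelConfig, build_model, chebyshev_basis_apply, fit,
                     count_parameters, forward, predict_iterated)
from .preprocess import make_windows, split_runs, zscore_per_run

__all__ = [
    "parameter_count",
    "chebyshev_recurrence_error",
    "linear_chebnet_operator_error",
    "iterated_matrix_power_error",
    "var_recovery",
    "graph_sensitivity_trial",
    "specificity_trial",
    "lag_lowpass_curve",
]

_FIT = dict(epochs=30, batch_size=256, learning_rate=0.02)


def support_connectome(support: np.ndarray) -> Connectome:
    P = support.shape[0]
    return Connectome(adjacency=support.astype(np.uint8),
                      density=float(support.sum() / (P * (P - 1))),
                      kind="functional")


def parameter_count(family: str, k: int, n_parcels: int, bias: bool = True) -> int:
    """Exact trainable-parameter count of a built model."""
    model = build_model(ModelConfig(family, k=k, bias=bias), n_parcels)
    return count_parameters(model)


def chebyshev_recurrence_error(seed: int = 0, P: int = 8, K: int = 5) -> float:
    """Max |recurrence - spectral-domain evaluation| of the Chebyshev basis."""
    rng = np.random.default_rng(seed)
    sop = scaled_laplacian(random_connectome(P, 0.4, seed=seed))
    x = rng.standard_normal((P, 3))
    terms = chebyshev_basis_apply(sop, x, K)
    lam, U = np.linalg.eigh(sop.scaled_laplacian)
    err = 0.0
    for j in range(K):
        Tj = np.cos(j * np.arccos(np.clip(lam, -1, 1)))
        dense = U @ (Tj[:, None] * (U.T @ x))
        err = max(err, float(np.abs(dense - terms[j]).max()))
    return err


def linear_chebnet_operator_error(seed: int = 0) -> float:
    """Max |linear Chebnet - explicitly assembled dense linear operator|."""
    rng = np.random.default_rng(seed)
    P, k, K = 6, 3, 3
    sop = scaled_laplacian(random_connectome(P, 0.4, seed=seed + 1))
    model = build_model(ModelConfig("chebnet", k=k, cheb_order=K, hidden_sizes=(4,),
                                    nonlinear=False, seed=seed), P, sop)
    win = rng.standard_normal((5, k, P))
    Lt = sop.scaled_laplacian
    Ts = [np.eye(P), Lt, 2 * Lt @ Lt - np.eye(P)]

    def layer(X, theta, b):
        return sum(Ts[j] @ X @ theta[j] for j in range(K)) + b

    expected = np.empty((5, P))
    for n in range(5):
        h = layer(win[n].T, model.params["theta0"], model.params["b0"])
        expected[n] = layer(h, model.params["theta1"], model.params["b1"])[:, 0]
    return float(np.abs(forward(model, win) - expected).max())


def iterated_matrix_power_error(seed: int = 0, l_max: int = 4) -> float:
    """Max |iterated linear prediction - matrix-power closed form|."""
    couplings, _ = make_coupling(8, 0.4, 1, 0.8, seed=seed)
    series = simulate_run(couplings, None, 1.0, 400, seed=seed + 1)
    model = build_model(ModelConfig("linear_multi", k=1, bias=False), 8)
    model.params["W0"] = couplings[0].T.copy()
    it = predict_iterated(model, series, l_max)
    err = 0.0
    for lag in range(1, l_max + 1):
        _, pred, _ = it.aligned(lag)
        expected = (np.linalg.matrix_power(couplings[0], lag)
                    @ series.data[:pred.shape[0]].T).T
        err = max(err, float(np.abs(pred - expected).max()))
    return err


def var_recovery(seed: int = 0, P: int = 10, T: int = 10_000):
    """Gradient-train a VAR(1) on simulated data; recover the generator.

    Returns ``(max_coeff_error, lag1_test_r2, theoretical_ceiling)`` where the
    ceiling is 1 - noise_var / signal_var estimated on the test run itself.
    """
    couplings, _ = make_coupling(P, 0.3, 1, 0.7, seed=seed)
    train = simulate_run(couplings, None, 1.0, T, seed=seed + 1)
    test = simulate_run(couplings, None, 1.0, 5000, seed=seed + 2)
    model = build_model(ModelConfig("linear_multi", k=1, seed=0), P)
    model = fit(model, make_windows([train], 1, 1), epochs=150, batch_size=512,
                learning_rate=0.02, seed=seed)
    max_err = float(np.abs(model.params["W0"].T - couplings[0]).max())
    recs = evaluate_model(model, [test], [1])
    r2 = float(np.mean([r.r2_mean for r in recs]))
    ceiling = float((1 - 1.0 / test.data.var(axis=0)).mean())
    return max_err, r2, ceiling


def _cheb_cfg():
    return ModelConfig("chebnet", k=3, cheb_order=3, hidden_sizes=(8,),
                       nonlinear=False, seed=0)


def graph_sensitivity_trial(seed: int, P: int = 30, n_random: int = 2):
    """One cohort seed of the graph-prior comparison.

    Trains a linear Chebnet with the true-support graph and with ``n_random``
    random graphs of equal density on the same runs; returns
    ``(r2_true_graph, r2_random_mean)`` at lag 1.
    """
    couplings, support = make_coupling(P, 0.10, 1, 0.9, seed=100 + seed)
    train = [zscore_per_run(simulate_run(couplings, None, 1.0, 360,
                                         seed=1000 + seed * 10 + r))
             for r in range(3)]
    test = [zscore_per_run(simulate_run(couplings, None, 1.0, 360,
                                        seed=2000 + seed * 10 + r))
            for r in range(2)]
    ws = make_windows(train, 3, 1)

    def score(sop):
        model = fit(build_model(_cheb_cfg(), P, sop), ws, seed=0, **_FIT)
        return float(np.mean([r.r2_mean for r in evaluate_model(model, test, [1])]))

    r2_true = score(scaled_laplacian(support_connectome(support)))
    r2_random = float(np.mean([
        score(scaled_laplacian(random_connectome(P, 0.10, seed=300 + seed * 10 + g)))
        for g in range(n_random)]))
    return r2_true, r2_random


def specificity_trial(divergence: float, seed: int):
    """One cohort seed of the subject-specificity analysis.

    Builds a 3-subject cohort at the requested coupling divergence, trains a
    VAR per subject, and returns ``(mean_intra_minus_inter_r2, n_rejected,
    n_pairs)`` at lag 1 (Wilcoxon over runs, BH across pairs).
    """
    cfg = CohortConfig(n_subjects=3, n_parcels=15, n_runs_per_condition={"movie": 11},
                       run_length=300, subject_divergence=divergence, seed=seed)
    runs, _ = generate_cohort(cfg)
    by: dict = {}
    for ts in runs:
        by.setdefault(ts.subject, []).append(zscore_per_run(ts))
    models, test_runs = {}, {}
    for s, rl in by.items():
        rl = sorted(rl, key=lambda t: (t.condition, t.run))
        split = split_runs(rl, 3 / 11)
        model = build_model(ModelConfig("linear_multi", k=1, seed=0), cfg.n_parcels)
        models[s] = fit(model, make_windows(list(split.train), 1, 1), seed=0, **_FIT)
        test_runs[s] = list(split.val) + list(split.test)
    diffs, tests = subject_specificity(models, test_runs, lags=[1])
    return (float(diffs["difference"].mean()), int(tests["reject"].sum()), len(tests))


def lag_lowpass_curve(n_seeds: int = 5, l_max: int = 6, cutoff_hz: float = 0.025,
                      base_seed: int = 900):
    """High-frequency power fraction of iterated predictions, by lag.

    Trains a VAR per cohort seed and returns the per-lag median (over all
    test runs of all seeds) of the fraction of predicted-signal power above
    ``cutoff_hz``.
    """
    values = {lag: [] for lag in range(1, l_max + 1)}
    for seed in range(n_seeds):
        cfg = CohortConfig(n_subjects=1, n_parcels=15,
                           n_runs_per_condition={"movie": 5}, run_length=480,
                           seed=base_seed + seed)
        runs, _ = generate_cohort(cfg)
        rl = sorted([zscore_per_run(t) for t in runs], key=lambda t: t.run)
        train, test = rl[:3], rl[3:]
        model = build_model(ModelConfig("linear_multi", k=1, seed=0), cfg.n_parcels)
        model = fit(model, make_windows(train, 1, 1), seed=0, **_FIT)
        for ts in test:
            it = predict_iterated(model, ts, l_max)
            for lag in range(1, l_max + 1):
                spec = power_spectrum(it.predicted_series(lag), ts.tr)
                values[lag].append(high_frequency_fraction(spec, cutoff_hz))
    return [float(np.median(values[lag])) for lag in range(1, l_max + 1)]
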