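"""Scoring and benchmark experiments: per-parcel R² by run and lag,
subject specificity, group-vs-individual comparison, data-scaling curves,
and the Wilcoxon / Benjamini-Hochberg statistics used to annotate them.

Aggregation convention: R² is first computed per parcel within a run, then
averaged over the evaluation parcel mask (``r2_mean``); runs are averaged
afterwards, never pooled. The R² baseline mean is the mean of the evaluated
target windows of that run, so a model that always predicts that mean scores
exactly zero.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import ParcelTimeSeries
from .errors import (AlignmentError, InvalidConfigError,
                     UndefinedScoreError)
from .models import ARModel, build_model, fit, predict_iterated
from .preprocess import make_windows

__all__ = [
    "EvalRecord",
    "r2_score",
    "evaluate_model",
    "subject_specificity",
    "group_vs_individual",
    "data_scaling",
    "wilcoxon_paired",
    "bh_fdr",
]


@dataclasses.dataclass(frozen=True)
class EvalRecord:
    model_subject: str
    data_subject: str
    run: str
    condition: str
    lag: int
    r2_per_parcel: np.ndarray
    r2_mean: float


def records_to_frame(records: Sequence[EvalRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {"model_subject": r.model_subject, "data_subject": r.data_subject,
         "run": r.run, "condition": r.condition, "lag": r.lag, "r2_mean": r.r2_mean}
        for r in records])


def r2_score(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    """Per-column coefficient of determination, 1 - SS_res / SS_tot.

    The baseline is each column's own mean over the evaluated samples; values
    below zero mean the prediction is worse than that constant baseline.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 2 or y_true.shape[0] < 2:
        raise InvalidConfigError("y_true and y_pred must be matching N x P with N >= 2")
    ss_tot = ((y_true - y_true.mean(axis=0)) ** 2).sum(axis=0)
    zero = np.flatnonzero(ss_tot == 0)
    if zero.size:
        raise UndefinedScoreError(f"zero-variance target column(s) {zero.tolist()}")
    ss_res = ((y_true - y_pred) ** 2).sum(axis=0)
    return 1.0 - ss_res / ss_tot


def evaluate_model(model: ARModel, runs: Sequence[ParcelTimeSeries],
                   lags: Sequence[int], mask: Optional[np.ndarray] = None,
                   model_subject: str = "") -> list:
    """One EvalRecord per (run, lag), using iterated single-step prediction."""
    lags = sorted(lags)
    records = []
    for ts in runs:
        it = predict_iterated(model, ts, max(lags))
        for lag in lags:
            _, pred, truth = it.aligned(lag)
            per_parcel = r2_score(truth, pred)
            masked = per_parcel if mask is None else per_parcel[np.asarray(mask)]
            records.append(EvalRecord(
                model_subject=model_subject or ts.subject, data_subject=ts.subject,
                run=ts.run, condition=ts.condition, lag=lag,
                r2_per_parcel=per_parcel, r2_mean=float(masked.mean())))
    return records


def subject_specificity(models: dict, test_runs_by_subject: dict,
                        lags: Sequence[int] = (1,), alpha: float = 0.05,
                        mask: Optional[np.ndarray] = None):
    """Intra-minus-inter subject R² differences with Wilcoxon + BH annotation.

    ``models`` maps subject -> trained ARModel; ``test_runs_by_subject`` maps
    subject -> matched test runs (same (condition, run) labels for everyone).
    For every ordered pair (i, j != i), each run contributes
    d = r2_mean(model_i on subject i) - r2_mean(model_i on subject j);
    a two-sided Wilcoxon signed-rank test is run per (pair, lag) over runs and
    BH-corrected across pairs within each lag.

    Returns ``(differences, tests)`` DataFrames.
    """
    subjects = sorted(models)
    if len(subjects) < 2:
        raise AlignmentError("subject specificity requires >= 2 subjects")
    run_keys = None
    for s in subjects:
        keys = sorted((ts.condition, ts.run) for ts in test_runs_by_subject[s])
        if run_keys is None:
            run_keys = keys
        elif keys != run_keys:
            raise AlignmentError(f"test runs of subject {s} do not match the others")

    # r2_mean per (model_subject, data_subject, run, lag)
    score: dict = {}
    for mi in subjects:
        for dj in subjects:
            for rec in evaluate_model(models[mi], test_runs_by_subject[dj], lags,
                                      mask=mask, model_subject=mi):
                score[(mi, dj, (rec.condition, rec.run), rec.lag)] = rec.r2_mean

    diff_rows = []
    for mi in subjects:
        for dj in subjects:
            if dj == mi:
                continue
            for key in run_keys:
                for lag in lags:
                    d = score[(mi, mi, key, lag)] - score[(mi, dj, key, lag)]
                    diff_rows.append({"model_subject": mi, "other_subject": dj,
                                      "condition": key[0], "run": key[1],
                                      "lag": lag, "difference": d})
    differences = pd.DataFrame(diff_rows)

    test_rows = []
    for lag in lags:
        sub = differences[differences["lag"] == lag]
        pairs, pvals, means = [], [], []
        for (mi, dj), grp in sub.groupby(["model_subject", "other_subject"]):
            d = grp["difference"].to_numpy()
            pairs.append((mi, dj))
            means.append(float(d.mean()))
            try:
                pvals.append(wilcoxon_paired(d, np.zeros_like(d)))
            except InvalidConfigError:  # too few runs for a valid test
                pvals.append(np.nan)
        finite = [i for i, p in enumerate(pvals) if np.isfinite(p)]
        p_adj = np.full(len(pvals), np.nan)
        reject = np.zeros(len(pvals), dtype=bool)
        if finite:
            rej, adj = bh_fdr([pvals[i] for i in finite], alpha)
            for slot, i in enumerate(finite):
                p_adj[i], reject[i] = adj[slot], rej[slot]
        for (mi, dj), mean_d, p, padj, rej in zip(pairs, means, pvals, p_adj, reject):
            test_rows.append({"model_subject": mi, "other_subject": dj, "lag": lag,
                              "mean_difference": mean_d, "p_value": p,
                              "p_adjusted": padj, "reject": bool(rej)})
    return differences, pd.DataFrame(test_rows)


def group_vs_individual(train_runs_by_subject: dict, test_runs_by_subject: dict,
                        config, total_train_runs: int, lags: Sequence[int] = (1,),
                        seed: int = 0, spectral_op=None, mask=None, **fit_kwargs):
    """Pooled (group) model vs. per-subject models at matched training budget.

    The group model trains on ``total_train_runs`` runs drawn balanced across
    subjects (ceil(total/n) from each, seeded, trimmed to the total); each
    individual model trains on ``total_train_runs`` of its own runs. All
    models are evaluated on each subject's test runs. Returns a tidy frame of
    per-run r2_mean for both models and their difference.
    """
    subjects = sorted(train_runs_by_subject)
    n_sub = len(subjects)
    per_subject = math.ceil(total_train_runs / n_sub)
    rng = np.random.default_rng(seed)
    pooled = []
    for s in subjects:
        runs = train_runs_by_subject[s]
        if len(runs) < min(per_subject, total_train_runs):
            raise InvalidConfigError(f"subject {s} has too few train runs")
        take = rng.choice(len(runs), size=min(per_subject, len(runs)), replace=False)
        pooled.extend(runs[i] for i in sorted(take))
    pooled = pooled[:total_train_runs]

    n_parcels = pooled[0].n_parcels
    group_model = fit(build_model(config, n_parcels, spectral_op),
                      make_windows(pooled, config.k, 1), seed=seed, **fit_kwargs)

    rows = []
    for s in subjects:
        runs = train_runs_by_subject[s]
        if len(runs) < total_train_runs:
            raise InvalidConfigError(
                f"subject {s} has {len(runs)} train runs < {total_train_runs}")
        take = rng.choice(len(runs), size=total_train_runs, replace=False)
        indiv_model = fit(build_model(config, n_parcels, spectral_op),
                          make_windows([runs[i] for i in sorted(take)], config.k, 1),
                          seed=seed, **fit_kwargs)
        indiv = evaluate_model(indiv_model, test_runs_by_subject[s], lags,
                               mask=mask, model_subject=s)
        group = evaluate_model(group_model, test_runs_by_subject[s], lags,
                               mask=mask, model_subject="group")
        for ri, gi in zip(indiv, group):
            rows.append({"subject": s, "run": ri.run, "condition": ri.condition,
                         "lag": ri.lag, "r2_individual": ri.r2_mean,
                         "r2_group": gi.r2_mean,
                         "difference": ri.r2_mean - gi.r2_mean})
    return pd.DataFrame(rows)


def data_scaling(train_runs: Sequence[ParcelTimeSeries],
                 val_runs: Sequence[ParcelTimeSeries], config,
                 run_counts: Sequence[int], repetitions: int = 5, seed: int = 0,
                 lags: Sequence[int] = (1,), spectral_op=None, mask=None,
                 **fit_kwargs) -> pd.DataFrame:
    """Learning curve: retrain from scratch on seeded random run subsets.

    For each count and repetition a subset of that many training runs is
    sampled without replacement (a fresh sub-seed per repetition) and the
    model is trained from scratch, then scored on the fixed validation runs.
    """
    if max(run_counts) > len(train_runs):
        raise InvalidConfigError(
            f"max run count {max(run_counts)} exceeds {len(train_runs)} available runs")
    n_parcels = train_runs[0].n_parcels
    rows = []
    for count in run_counts:
        for rep in range(repetitions):
            sub_seed = (seed * 100_003 + count * 101 + rep) % (2 ** 31)
            rng = np.random.default_rng(sub_seed)
            take = sorted(rng.choice(len(train_runs), size=count, replace=False))
            model = fit(build_model(config, n_parcels, spectral_op),
                        make_windows([train_runs[i] for i in take], config.k, 1),
                        seed=sub_seed, **fit_kwargs)
            for rec in evaluate_model(model, val_runs, lags, mask=mask):
                rows.append({"run_count": count, "repetition": rep, "run": rec.run,
                             "lag": rec.lag, "r2_mean": rec.r2_mean})
    return pd.DataFrame(rows)


def _exact_wilcoxon_p(d: np.ndarray) -> float:
    """Exact two-sided signed-rank p via the rank-sum distribution.

    Midranks of tied |d| are doubled to integers and the null distribution of
    the positive-rank sum is built by dynamic programming over sign flips.
    """
    ranks = stats.rankdata(np.abs(d))
    int_ranks = np.round(2 * ranks).astype(int)
    w2 = int(round(2 * ranks[d > 0].sum()))
    total = int(int_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in int_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    p_le = counts[:w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_paired(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired samples.

    Zero differences are removed first; if all differences are zero the test
    is degenerate and p = 1 is returned with a warning. The exact null
    distribution (supporting midrank ties) is used for n <= 25, the normal
    approximation with tie correction above.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidConfigError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; returning p = 1", stacklevel=2)
        return 1.0
    if n < 5:
        raise InvalidConfigError("need >= 5 nonzero differences")
    if n <= 25:
        return _exact_wilcoxon_p(d)
    ranks = stats.rankdata(np.abs(d))
    w = ranks[d > 0].sum()
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts ** 3 - tie_counts).sum() / 48.0
    z = (w - mean) / math.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def bh_fdr(pvalues: Sequence[float], alpha: float = 0.05):
    """Benjamini-Hochberg step-up FDR correction.

    Returns ``(reject_flags, adjusted_p)``; empty input yields empty arrays.
    """
    pvalues = np.asarray(list(pvalues), dtype=float)
    if pvalues.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise InvalidConfigError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(pvalues, alpha=alpha, method="fdr_bh")
    return reject, p_adj
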