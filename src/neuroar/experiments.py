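"""Experiment-suite orchestration: simulate -> preprocess -> graphs -> train
-> evaluate -> analyze, with every artifact written alongside the seed and a
hash of the configuration so a rerun is byte-identical."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import dynamics as dyn
from .cohort import generate_cohort
from .config import ExperimentConfig, config_to_dict, validate_config
from .errors import NeuroarError
from .evaluation import (bh_fdr, data_scaling, evaluate_model,
                         group_vs_individual, records_to_frame,
                         subject_specificity, wilcoxon_paired)
from .graphs import (binarize_top_density, functional_connectome,
                     random_connectome, scaled_laplacian, spatial_connectome)
from .models import build_model, fit, predict_iterated
from .preprocess import (estimate_shared_response, make_windows,
                         regress_out_shared, split_runs, zscore_per_run)

__all__ = ["run_experiment_suite", "plan_experiment_suite"]

logger = logging.getLogger("neuroar")

_CSV_KW = dict(index=False, float_format="%.12g")


def _config_hash(cfg: ExperimentConfig) -> str:
    blob = json.dumps(config_to_dict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _subseed(base: int, *parts) -> int:
    s = int(base) % (2 ** 31)
    for p in parts:
        token = str(p).encode()
        s = (s * 1_000_003 + int.from_bytes(hashlib.sha256(token).digest()[:4], "big")) \
            % (2 ** 31)
    return s


def _preprocess_run(ts, cfg: ExperimentConfig):
    return zscore_per_run(ts)


def _prepare(cfg: ExperimentConfig):
    """Simulate the cohort, normalize each run, and split per subject."""
    runs, truth = generate_cohort(cfg.cohort)
    by_subject: dict = {}
    for ts in runs:
        by_subject.setdefault(ts.subject, []).append(_preprocess_run(ts, cfg))
    splits = {}
    for subject, run_list in by_subject.items():
        run_list = sorted(run_list, key=lambda t: (t.condition, t.run))
        splits[subject] = split_runs(run_list, cfg.train_fraction)
    return splits, truth


def _graph_for(cfg, subject, split, truth, kind, seed=0):
    if kind == "functional":
        weights = functional_connectome(split.train)
        return binarize_top_density(weights, cfg.graph_density,
                                    absolute=cfg.absolute_correlation)
    if kind == "spatial":
        return spatial_connectome(truth.parcel_coords, cfg.graph_density)
    if kind == "random":
        return random_connectome(cfg.cohort.n_parcels, cfg.graph_density, seed=seed)
    if kind == "support":
        n_pairs = cfg.cohort.n_parcels * (cfg.cohort.n_parcels - 1) / 2
        from .graphs import Connectome
        return Connectome(adjacency=truth.support_graph,
                          density=float(truth.support_graph.sum() / 2 / n_pairs),
                          kind="functional")
    raise NeuroarError(f"unknown graph kind {kind!r}")


def _fit_kwargs(cfg):
    return dict(epochs=cfg.epochs, batch_size=cfg.batch_size,
                learning_rate=cfg.learning_rate)


def _train_one(cfg, model_cfg, train_runs, spectral_op, seed):
    model = build_model(model_cfg, train_runs[0].n_parcels, spectral_op)
    return fit(model, make_windows(train_runs, model_cfg.k, 1), seed=seed,
               **_fit_kwargs(cfg))


def _annotate_adjacent(detail: pd.DataFrame, group_col: str) -> pd.DataFrame:
    """Wilcoxon between successive groups (ranked by mean) per lag, BH-corrected."""
    rows = []
    for lag, sub in detail.groupby("lag"):
        means = sub.groupby(group_col)["r2_mean"].mean().sort_values(ascending=False)
        order = list(means.index)
        pvals, pairs = [], []
        for a, b in zip(order[:-1], order[1:]):
            xa = sub[sub[group_col] == a].sort_values(["subject", "run"])["r2_mean"].to_numpy()
            xb = sub[sub[group_col] == b].sort_values(["subject", "run"])["r2_mean"].to_numpy()
            if xa.size == xb.size and xa.size >= 5:
                pvals.append(wilcoxon_paired(xa, xb))
            else:
                pvals.append(np.nan)
            pairs.append((a, b))
        finite = [i for i, p in enumerate(pvals) if np.isfinite(p)]
        p_adj = np.full(len(pvals), np.nan)
        reject = np.zeros(len(pvals), dtype=bool)
        if finite:
            rej, adj = bh_fdr([pvals[i] for i in finite])
            for slot, i in enumerate(finite):
                p_adj[i], reject[i] = adj[slot], rej[slot]
        for (a, b), p, padj, rej in zip(pairs, pvals, p_adj, reject):
            rows.append({"lag": lag, "better": a, "worse": b,
                         "mean_better": means[a], "mean_worse": means[b],
                         "p_value": p, "p_adjusted": padj, "reject": bool(rej)})
    return pd.DataFrame(rows)


def _eval_frame(model, subject, split, lags, label_col=None, label=None):
    recs = evaluate_model(model, list(split.test), lags, model_subject=subject)
    frame = records_to_frame(recs).rename(columns={"data_subject": "subject"})
    if label_col:
        frame[label_col] = label
    return frame


# --------------------------------------------------------------------------
# individual experiments; each returns {csv_name: DataFrame}
# --------------------------------------------------------------------------

def _exp_model_comparison(cfg, splits, truth):
    frames = []
    for model_cfg in cfg.model_grid:
        for subject, split in sorted(splits.items()):
            spectral_op = None
            if model_cfg.family == "chebnet":
                spectral_op = scaled_laplacian(
                    _graph_for(cfg, subject, split, truth, cfg.graph_kind))
            model = _train_one(cfg, model_cfg, list(split.train), spectral_op,
                               _subseed(cfg.seed, "model_comparison", model_cfg.family,
                                        subject))
            frame = _eval_frame(model, subject, split, cfg.lags,
                                "family", model_cfg.family)
            frames.append(frame)
    detail = pd.concat(frames, ignore_index=True)
    summary = (detail.groupby(["family", "lag"])["r2_mean"].mean()
               .reset_index().sort_values(["lag", "r2_mean"], ascending=[True, False]))
    tests = _annotate_adjacent(detail, "family")
    return {"model_comparison_detail.csv": detail,
            "model_comparison_summary.csv": summary,
            "model_comparison_tests.csv": tests}


def _chebnet_cfg(cfg):
    for mc in cfg.model_grid:
        if mc.family == "chebnet":
            return mc
    raise NeuroarError("this experiment needs a chebnet entry in model_grid")


def _exp_graph_sensitivity(cfg, splits, truth):
    model_cfg = _chebnet_cfg(cfg)
    frames = []
    for subject, split in sorted(splits.items()):
        for kind in ("functional", "spatial", "random"):
            trials = range(cfg.n_random_graph_trials) if kind == "random" else [0]
            per_trial = []
            for trial in trials:
                conn = _graph_for(cfg, subject, split, truth, kind,
                                  seed=_subseed(cfg.seed, "graph", subject, trial))
                model = _train_one(cfg, model_cfg, list(split.train),
                                   scaled_laplacian(conn),
                                   _subseed(cfg.seed, "graph_fit", subject, kind, trial))
                per_trial.append(_eval_frame(model, subject, split, cfg.lags))
            frame = per_trial[0].copy()
            if len(per_trial) > 1:  # random graphs: average the trials' scores
                frame["r2_mean"] = np.mean([f["r2_mean"].to_numpy() for f in per_trial],
                                           axis=0)
            frame["graph"] = kind
            frames.append(frame)
    detail = pd.concat(frames, ignore_index=True)
    summary = detail.groupby(["graph", "lag"])["r2_mean"].mean().reset_index()
    tests = _annotate_adjacent(detail, "graph")
    return {"graph_sensitivity_detail.csv": detail,
            "graph_sensitivity_summary.csv": summary,
            "graph_sensitivity_tests.csv": tests}


def _exp_linearity_sensitivity(cfg, splits, truth):
    import dataclasses as dc
    model_cfg = _chebnet_cfg(cfg)
    frames = []
    for subject, split in sorted(splits.items()):
        spectral_op = scaled_laplacian(
            _graph_for(cfg, subject, split, truth, cfg.graph_kind))
        for nonlinear in (True, False):
            variant = dc.replace(model_cfg, nonlinear=nonlinear)
            model = _train_one(cfg, variant, list(split.train), spectral_op,
                               _subseed(cfg.seed, "linearity", subject, nonlinear))
            frames.append(_eval_frame(model, subject, split, cfg.lags, "variant",
                                      "nonlinear" if nonlinear else "linear"))
    detail = pd.concat(frames, ignore_index=True)
    summary = detail.groupby(["variant", "lag"])["r2_mean"].mean().reset_index()
    tests = _annotate_adjacent(detail, "variant")
    return {"linearity_detail.csv": detail, "linearity_summary.csv": summary,
            "linearity_tests.csv": tests}


def _reference_cfg(cfg):
    try:
        return _chebnet_cfg(cfg)
    except NeuroarError:
        return cfg.model_grid[0]


def _exp_data_scaling(cfg, splits, truth):
    model_cfg = _reference_cfg(cfg)
    frames = []
    for subject, split in sorted(splits.items()):
        n_train = len(split.train)
        counts = cfg.data_scaling_run_counts or tuple(range(4, n_train + 1, 4))
        counts = tuple(c for c in counts if c <= n_train) or (n_train,)
        spectral_op = None
        if model_cfg.family == "chebnet":
            spectral_op = scaled_laplacian(
                _graph_for(cfg, subject, split, truth, cfg.graph_kind))
        table = data_scaling(list(split.train), list(split.val), model_cfg,
                             counts, repetitions=cfg.data_scaling_repetitions,
                             seed=_subseed(cfg.seed, "scaling", subject),
                             lags=cfg.lags, spectral_op=spectral_op,
                             **_fit_kwargs(cfg))
        table["subject"] = subject
        frames.append(table)
    detail = pd.concat(frames, ignore_index=True)
    summary = detail.groupby(["run_count", "lag"])["r2_mean"].mean().reset_index()
    return {"data_scaling_detail.csv": detail, "data_scaling_summary.csv": summary}


def _train_per_subject(cfg, splits, truth, tag):
    model_cfg = _reference_cfg(cfg)
    models = {}
    for subject, split in sorted(splits.items()):
        spectral_op = None
        if model_cfg.family == "chebnet":
            spectral_op = scaled_laplacian(
                _graph_for(cfg, subject, split, truth, cfg.graph_kind))
        models[subject] = _train_one(cfg, model_cfg, list(split.train), spectral_op,
                                     _subseed(cfg.seed, tag, subject))
    return models


def _exp_subject_specificity(cfg, splits, truth):
    models = _train_per_subject(cfg, splits, truth, "specificity")
    test_runs = {s: list(split.test) for s, split in splits.items()}
    differences, tests = subject_specificity(models, test_runs, lags=cfg.lags)
    return {"subject_specificity_differences.csv": differences,
            "subject_specificity_tests.csv": tests}


def _exp_group_model(cfg, splits, truth):
    model_cfg = _reference_cfg(cfg)
    spectral_op = None
    if model_cfg.family == "chebnet":
        first = sorted(splits)[0]
        spectral_op = scaled_laplacian(
            _graph_for(cfg, first, splits[first], truth, cfg.graph_kind))
    total = cfg.group_total_train_runs or min(len(s.train) for s in splits.values())
    table = group_vs_individual({s: list(sp.train) for s, sp in splits.items()},
                                {s: list(sp.test) for s, sp in splits.items()},
                                model_cfg, total, lags=cfg.lags,
                                seed=_subseed(cfg.seed, "group"),
                                spectral_op=spectral_op, **_fit_kwargs(cfg))
    summary = table.groupby("lag")[["r2_individual", "r2_group", "difference"]] \
        .mean().reset_index()
    return {"group_vs_individual_detail.csv": table,
            "group_vs_individual_summary.csv": summary}


def _exp_shared_response_ablation(cfg, splits, truth):
    model_cfg = _reference_cfg(cfg)
    all_runs = {s: list(sp.train) + list(sp.val) + list(sp.test)
                for s, sp in splits.items()}
    frames = []
    for subject, split in sorted(splits.items()):
        shared = estimate_shared_response(all_runs, subject)
        def residual(ts):
            return regress_out_shared(ts, shared[(ts.condition, ts.run)])
        spectral_op = None
        if model_cfg.family == "chebnet":
            spectral_op = scaled_laplacian(
                _graph_for(cfg, subject, split, truth, cfg.graph_kind))
        for variant, transform in (("whole_signal", lambda t: t),
                                   ("intrinsic", residual)):
            train = [transform(t) for t in split.train]
            test = [transform(t) for t in split.test]
            model = _train_one(cfg, model_cfg, train, spectral_op,
                               _subseed(cfg.seed, "ablation", subject, variant))
            recs = evaluate_model(model, test, cfg.lags, model_subject=subject)
            frame = records_to_frame(recs).rename(columns={"data_subject": "subject"})
            frame["variant"] = variant
            frames.append(frame)
    detail = pd.concat(frames, ignore_index=True)
    summary = detail.groupby(["variant", "lag"])["r2_mean"].mean().reset_index()
    tests = _annotate_adjacent(detail, "variant")
    return {"shared_response_detail.csv": detail,
            "shared_response_summary.csv": summary,
            "shared_response_tests.csv": tests}


def _exp_dynamics(cfg, splits, truth):
    models = _train_per_subject(cfg, splits, truth, "dynamics")
    l_max = max(cfg.lags)
    spec_rows, seed_rows = [], []
    for subject, split in sorted(splits.items()):
        for ts in split.test:
            it = predict_iterated(models[subject], ts, l_max)
            base = dyn.power_spectrum(ts.data, ts.tr)
            spec_rows.append({"subject": subject, "run": ts.run, "source": "original",
                              "lag": 0, "high_freq_fraction":
                              dyn.high_frequency_fraction(base, 0.025)})
            for lag in cfg.lags:
                spec = dyn.power_spectrum(it.predicted_series(lag), ts.tr,
                                          source=f"predicted(lag={lag})")
                spec_rows.append({"subject": subject, "run": ts.run,
                                  "source": spec.source, "lag": lag,
                                  "high_freq_fraction":
                                  dyn.high_frequency_fraction(spec, 0.025)})
            # seed map overlap: original vs lag-1 predicted seed signal
            t_idx, pred, _ = it.aligned(1)
            ref = ts.data[t_idx]
            orig_map = dyn.seed_connectivity(ref[:, cfg.seed_parcel], ref)
            pred_map = dyn.seed_connectivity(pred[:, cfg.seed_parcel], ref)
            m_orig = dyn.threshold_top_fraction(orig_map, 0.1)
            m_pred = dyn.threshold_top_fraction(pred_map, 0.1)
            jaccard = (m_orig & m_pred).sum() / (m_orig | m_pred).sum()
            seed_rows.append({"subject": subject, "run": ts.run,
                              "seed_parcel": cfg.seed_parcel, "lag": 1,
                              "jaccard_top10": float(jaccard)})
    return {"dynamics_spectra.csv": pd.DataFrame(spec_rows),
            "dynamics_seed_overlap.csv": pd.DataFrame(seed_rows)}


_EXPERIMENTS = {
    "model_comparison": _exp_model_comparison,
    "graph_sensitivity": _exp_graph_sensitivity,
    "linearity_sensitivity": _exp_linearity_sensitivity,
    "data_scaling": _exp_data_scaling,
    "subject_specificity": _exp_subject_specificity,
    "group_model": _exp_group_model,
    "shared_response_ablation": _exp_shared_response_ablation,
    "dynamics": _exp_dynamics,
}


def plan_experiment_suite(config) -> list:
    """The ordered stage list a run would execute, without executing it."""
    cfg = validate_config(config)
    return ["simulate", "preprocess", "graphs"] + \
        [name for name in _EXPERIMENTS if name in cfg.experiments]


def run_experiment_suite(config, out_dir=None) -> dict:
    """Execute the enabled experiments and write one CSV bundle.

    Reruns with an identical configuration and seed produce byte-identical
    CSVs. Returns {filename: DataFrame} of everything written; a
    ``manifest.json`` records the seed, config hash and file list.
    """
    cfg = validate_config(config)
    out = Path(out_dir or cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("stage=simulate seed=%d", cfg.seed)
    splits, truth = _prepare(cfg)
    written: dict = {}
    for name in cfg.experiments:
        logger.info("stage=%s start", name)
        try:
            tables = _EXPERIMENTS[name](cfg, splits, truth)
        except Exception:
            logger.exception("stage=%s failed; partial outputs kept in %s", name, out)
            raise
        for fname, frame in tables.items():
            frame.to_csv(out / fname, **_CSV_KW)
            written[fname] = frame
            logger.info("stage=%s wrote %s rows=%d", name, fname, len(frame))
    manifest = {"seed": cfg.seed, "config_hash": _config_hash(cfg),
                "config": config_to_dict(cfg), "files": sorted(written)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                                  default=str))
    return written
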