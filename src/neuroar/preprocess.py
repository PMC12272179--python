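"""Run normalization, high-pass filtering, run splitting, windowing and
shared-response estimation/regression.

The pipeline order matches the benchmark's contract: each run is z-scored
(and optionally high-passed) on its own, runs are split into train /
validation / test sets by acquisition order, and supervised windows are only
then extracted, never spanning a run boundary.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np

from .cohort import ParcelTimeSeries
from .errors import (DegenerateInputError, EmptyWindowSetError,
                     InsufficientSubjectsError, InvalidConfigError,
                     InvalidSplitError)

__all__ = [
    "RunSplit",
    "WindowSet",
    "zscore_per_run",
    "dct_highpass",
    "split_runs",
    "make_windows",
    "estimate_shared_response",
    "regress_out_shared",
]


@dataclasses.dataclass(frozen=True)
class RunSplit:
    train: tuple
    val: tuple
    test: tuple


@dataclasses.dataclass
class WindowSet:
    """Supervised pairs: a k-step window of all parcels -> target at lag l."""

    inputs: np.ndarray    # (N, k, P)
    targets: np.ndarray   # (N, P)
    k: int
    lag: int
    provenance: list      # (subject, run) per sample

    @property
    def n_samples(self) -> int:
        return self.inputs.shape[0]


def zscore_per_run(series: ParcelTimeSeries) -> ParcelTimeSeries:
    """Standardize each parcel to zero mean, unit population SD within the run."""
    data = series.data
    if data.shape[0] < 2:
        raise InvalidConfigError("need at least 2 time points to z-score")
    sd = data.std(axis=0)  # population (ddof=0) by convention
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise DegenerateInputError(
            f"constant parcel column(s) {constant.tolist()} cannot be z-scored "
            f"(subject={series.subject}, run={series.run})")
    return series.with_data((data - data.mean(axis=0)) / sd)


def _dct_basis(T: int, n: int) -> np.ndarray:
    """DCT-II regressor columns 1..n (the constant term is handled separately)."""
    t = np.arange(T)
    ks = np.arange(1, n + 1)
    return np.cos(np.pi * np.outer(2 * t + 1, ks) / (2 * T))


def dct_highpass(series: ParcelTimeSeries, cutoff_hz: float) -> ParcelTimeSeries:
    """Remove slow drifts by projecting out low-frequency discrete-cosine regressors.

    The regressors are the DCT-II basis functions with frequency
    ``k / (2 T tr)`` strictly below ``cutoff_hz``, plus the constant; their
    least-squares fit is subtracted from every parcel.
    """
    T = series.n_timepoints
    nyquist = 1.0 / (2.0 * series.tr)
    if cutoff_hz >= nyquist:
        raise InvalidConfigError(f"cutoff_hz={cutoff_hz} must be below Nyquist {nyquist:.4g}")
    n = int(math.ceil(2 * T * series.tr * cutoff_hz)) - 1  # largest k with freq < cutoff
    centered = series.data - series.data.mean(axis=0)
    if n < 1:
        warnings.warn("run too short to form any discrete-cosine regressor below "
                      "the cutoff; returning the mean-centered input", stacklevel=2)
        return series.with_data(centered)
    basis = _dct_basis(T, n)
    coef, *_ = np.linalg.lstsq(basis, centered, rcond=None)
    return series.with_data(centered - basis @ coef)


def split_runs(runs: Sequence, train_fraction: float) -> RunSplit:
    """Split runs (in acquisition order) into train, then alternating val/test.

    The first ``ceil(train_fraction * n)`` runs form the training set; within
    the remainder, even 0-based positions go to validation and odd ones to
    test (the 0-based reading of an even/odd episode split).
    """
    runs = list(runs)
    if len(runs) < 3:
        raise InvalidSplitError("need at least 3 runs to split")
    n_train = math.ceil(train_fraction * len(runs))
    rest = runs[n_train:]
    if not rest:
        raise InvalidSplitError("train_fraction leaves no runs for validation/test")
    return RunSplit(train=tuple(runs[:n_train]),
                    val=tuple(rest[0::2]),
                    test=tuple(rest[1::2]))


def make_windows(series: Sequence[ParcelTimeSeries], k: int, lag: int = 1) -> WindowSet:
    """Extract all (k-step window -> target at lag l) pairs, per run.

    A run of length T yields ``T - k - lag + 1`` samples; runs shorter than
    ``k + lag`` are skipped with a warning. Sample i's window covers rows
    ``i .. i+k-1`` and its target is row ``i + k - 1 + lag``.
    """
    if k < 1 or lag < 1:
        raise InvalidConfigError("k and lag must be >= 1")
    inputs, targets, provenance = [], [], []
    for ts in series:
        T = ts.n_timepoints
        n = T - k - lag + 1
        if n < 1:
            warnings.warn(f"run {ts.subject}/{ts.run} too short for k={k}, lag={lag}; skipped",
                          stacklevel=2)
            continue
        sw = np.lib.stride_tricks.sliding_window_view(ts.data, k, axis=0)  # (T-k+1, P, k)
        inputs.append(np.ascontiguousarray(sw[:n].transpose(0, 2, 1)))
        targets.append(ts.data[k - 1 + lag:])
        provenance.extend([(ts.subject, ts.run)] * n)
    if not inputs:
        raise EmptyWindowSetError(f"no run long enough for k={k}, lag={lag}")
    return WindowSet(inputs=np.concatenate(inputs), targets=np.concatenate(targets),
                     k=k, lag=lag, provenance=provenance)


def estimate_shared_response(runs_by_subject: dict, held_out_subject: str) -> dict:
    """Leave-one-subject-out shared response: the element-wise mean, per
    (condition, run), of every other subject's (already normalized) series.

    ``runs_by_subject`` maps subject -> list of ParcelTimeSeries. Returns a
    dict (condition, run) -> (T, P) matrix.
    """
    others = {s: r for s, r in runs_by_subject.items() if s != held_out_subject}
    if len(others) < 2:
        raise InsufficientSubjectsError(
            f"need >= 2 subjects besides {held_out_subject!r}, found {len(others)}")
    grouped: dict = {}
    for subject, run_list in others.items():
        for ts in run_list:
            grouped.setdefault((ts.condition, ts.run), []).append(ts.data)
    shared = {}
    for key, stack in grouped.items():
        if len(stack) < 2:
            raise InsufficientSubjectsError(
                f"run {key} present for fewer than 2 other subjects")
        shared[key] = np.mean(stack, axis=0)
    return shared


def regress_out_shared(series: ParcelTimeSeries, shared: np.ndarray) -> ParcelTimeSeries:
    """Per-parcel OLS of the subject signal on [intercept, shared column];
    returns the residuals (the subject's intrinsic activity)."""
    shared = np.asarray(shared, dtype=float)
    if shared.shape != series.data.shape:
        raise InvalidConfigError(
            f"shared shape {shared.shape} != series shape {series.data.shape}")
    T, P = series.data.shape
    residuals = np.empty_like(series.data)
    for j in range(P):
        col = shared[:, j]
        if np.ptp(col) == 0:
            warnings.warn(f"constant shared column {j}: intercept-only regression",
                          stacklevel=2)
            design = np.ones((T, 1))
        else:
            design = np.column_stack([np.ones(T), col])
        coef, *_ = np.linalg.lstsq(design, series.data[:, j], rcond=None)
        residuals[:, j] = series.data[:, j] - design @ coef
    return series.with_data(residuals)
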