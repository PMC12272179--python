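"""Prediction-dynamics analyses: power spectra of predicted signals by lag,
and seed-based connectivity computed from predicted parcel signals."""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np

from .errors import InvalidConfigError, UndefinedScoreError

__all__ = [
    "Spectrum",
    "power_spectrum",
    "high_frequency_fraction",
    "seed_connectivity",
    "threshold_top_fraction",
]


@dataclasses.dataclass(frozen=True)
class Spectrum:
    freqs: np.ndarray   # one-sided Hz grid, strictly increasing, <= Nyquist
    power: np.ndarray   # (F, P) per-parcel periodogram values
    source: str = "original"


def power_spectrum(series: np.ndarray, tr: float, source: str = "original") -> Spectrum:
    """Plain per-column periodogram |DFT|² on the one-sided frequency grid.

    No windowing, tapering or detrending is applied.
    """
    data = np.asarray(series, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    if data.shape[0] < 8:
        raise InvalidConfigError("need at least 8 time points for a spectrum")
    spectrum = np.fft.rfft(data, axis=0)
    return Spectrum(freqs=np.fft.rfftfreq(data.shape[0], d=tr),
                    power=np.abs(spectrum) ** 2, source=source)


def high_frequency_fraction(spectrum: Spectrum, cutoff_hz: float) -> float:
    """Fraction of total spectral power lying strictly above ``cutoff_hz``."""
    if not spectrum.freqs[0] <= cutoff_hz <= spectrum.freqs[-1]:
        raise InvalidConfigError("cutoff outside the spectrum's frequency grid")
    total = spectrum.power.sum()
    if total == 0:
        raise UndefinedScoreError("zero total power: fraction undefined")
    above = spectrum.power[spectrum.freqs > cutoff_hz].sum()
    return float(above / total)


def seed_connectivity(seed_signal: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Pearson correlation of one (possibly predicted) seed signal against
    every original parcel column; undefined entries come back as NaN with a
    warning, never silently zeroed."""
    seed = np.asarray(seed_signal, dtype=float).ravel()
    ref = np.asarray(reference, dtype=float)
    if ref.shape[0] != seed.size:
        raise InvalidConfigError("seed and reference lengths are not aligned")
    seed_c = seed - seed.mean()
    ref_c = ref - ref.mean(axis=0)
    seed_ss = float(seed_c @ seed_c)
    ref_ss = (ref_c ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (ref_c.T @ seed_c) / np.sqrt(seed_ss * ref_ss)
    undefined = ~np.isfinite(corr)
    if seed_ss == 0:
        undefined[:] = True
    if undefined.any():
        warnings.warn(f"{int(undefined.sum())} undefined correlation(s) "
                      "(constant seed or parcel); returned as NaN", stacklevel=2)
        corr = np.where(undefined, np.nan, corr)
    return corr


def threshold_top_fraction(values: np.ndarray, fraction: float) -> np.ndarray:
    """Boolean mask of the ceil(fraction * P) highest values; ties keep the
    lowest index."""
    if not 0.0 < fraction <= 1.0:
        raise InvalidConfigError("fraction must lie in (0, 1]")
    values = np.asarray(values, dtype=float)
    n_keep = math.ceil(fraction * values.size)
    order = np.argsort(-values, kind="stable")  # stable: equal values keep index order
    mask = np.zeros(values.size, dtype=bool)
    mask[order[:n_keep]] = True
    return mask
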