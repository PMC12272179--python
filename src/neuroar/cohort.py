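"""Synthetic multi-subject cohort generator for parcel-level BOLD-like dynamics.

The generator is a stable vector auto-regression (VAR) on a sparse undirected
coupling graph. Each subject owns a coupling stack obtained by mixing a common
base with a subject-specific perturbation; each (condition, run) owns a
stimulus-evoked, low-frequency "shared response" added identically to every
subject's recursion, mimicking what synchronized naturalistic stimulation
contributes to BOLD signals. Rest-like conditions carry no shared component.

Nothing here models hemodynamics, physiological noise or motion; the point is
a ground-truthed stand-in with the statistical structure (per-run scale, slow
shared signal, subject-specific intrinsic dynamics, sparse spatial coupling)
the downstream benchmark assumes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ExplosionError, InvalidConfigError

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "ParcelTimeSeries",
    "make_coupling",
    "make_shared_response",
    "simulate_run",
    "generate_cohort",
    "parcel_coordinates",
    "write_cohort",
    "read_cohort",
]

#: conditions whose label starts with this prefix get a zero shared response
REST_PREFIX = "rest"


@dataclasses.dataclass(frozen=True)
class ParcelTimeSeries:
    """One run's time x parcel signal matrix with its acquisition labels."""

    subject: str
    run: str
    condition: str
    data: np.ndarray  # (T, P), float
    tr: float = 1.49

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise InvalidConfigError("ParcelTimeSeries.data must be 2-D (time x parcels)")
        if not np.all(np.isfinite(data)):
            raise InvalidConfigError("ParcelTimeSeries.data contains non-finite values")
        object.__setattr__(self, "data", data)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "ParcelTimeSeries":
        return dataclasses.replace(self, data=data)


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    """Generation parameters for a synthetic cohort.

    Defaults give the desk-scale cohort: 6 subjects, 30 parcels, one
    movie-like condition of 68 runs of 480 time points at TR 1.49 s (the
    length of a ~12 min acquisition run); a full 197-parcel configuration is
    a parameter change only.
    """

    n_subjects: int = 6
    n_parcels: int = 30
    n_runs_per_condition: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"movie": 68})
    run_length: int = 480
    tr: float = 1.49
    coupling_density: float = 0.1
    coupling_order: int = 1
    coupling_homogeneity: float = 0.7
    spectral_radius: float = 0.9
    shared_amplitude: float = 0.5
    shared_cutoff_hz: float = 0.05
    subject_divergence: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise InvalidConfigError("n_subjects must be >= 1")
        if self.n_parcels < 2:
            raise InvalidConfigError("n_parcels must be >= 2")
        if self.run_length <= self.coupling_order:
            raise InvalidConfigError("run_length must exceed coupling_order")
        if not 0.0 < self.spectral_radius < 1.0:
            raise InvalidConfigError("spectral_radius must lie in (0, 1)")
        if not 0.0 < self.coupling_density <= 1.0:
            raise InvalidConfigError("coupling_density must lie in (0, 1]")
        if self.shared_amplitude < 0:
            raise InvalidConfigError("shared_amplitude must be >= 0")
        if not 0.0 <= self.subject_divergence <= 1.0:
            raise InvalidConfigError("subject_divergence must lie in [0, 1]")


@dataclasses.dataclass
class GroundTruth:
    """Everything the simulator knows that an analyst normally would not."""

    couplings: np.ndarray          # (n_subjects, order, P, P)
    support_graph: np.ndarray      # (P, P) binary symmetric, zero diagonal
    shared_responses: dict         # (condition, run_index) -> (T, P)
    parcel_coords: np.ndarray      # (P, 3)


def _companion_spectral_radius(couplings: np.ndarray) -> float:
    """Spectral radius of the VAR(p) companion matrix of a (p, P, P) stack."""
    order, P, _ = couplings.shape
    companion = np.zeros((order * P, order * P))
    companion[:P] = np.concatenate(list(couplings), axis=1)
    if order > 1:
        companion[P:, :-P] = np.eye((order - 1) * P)
    return float(np.max(np.abs(np.linalg.eigvals(companion))))


def _rescale_to_radius(couplings: np.ndarray, radius: float) -> np.ndarray:
    """Scale A_j by c**j so the companion spectral radius becomes `radius` exactly."""
    rho = _companion_spectral_radius(couplings)
    if not np.isfinite(rho) or rho == 0.0:
        raise FloatingPointError("degenerate coupling draw (zero or non-finite radius)")
    c = radius / rho
    scales = c ** np.arange(1, couplings.shape[0] + 1)
    return couplings * scales[:, None, None]


def _draw_support(P: int, density: float, rng: np.random.Generator) -> np.ndarray:
    n_pairs = P * (P - 1) // 2
    m = int(round(density * n_pairs))
    iu = np.triu_indices(P, k=1)
    chosen = rng.choice(n_pairs, size=m, replace=False)
    support = np.zeros((P, P), dtype=np.uint8)
    support[iu[0][chosen], iu[1][chosen]] = 1
    return support | support.T


def _draw_stack(P, order, support, homogeneity, rng):
    """One coupling draw: homogeneous diffusion along the graph plus
    heterogeneous per-edge weights, both normalized before mixing."""
    mask = support.astype(float) + np.eye(P)
    deg = support.sum(axis=1).astype(float)
    d_inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
    diffusion = d_inv_sqrt[:, None] * support * d_inv_sqrt[None, :] + 0.5 * np.eye(P)
    diffusion = diffusion / max(np.max(np.abs(np.linalg.eigvals(diffusion))), 1e-12)
    stack = np.empty((order, P, P))
    for j in range(order):
        hetero = rng.standard_normal((P, P)) * mask
        rho = np.max(np.abs(np.linalg.eigvals(hetero)))
        hetero = hetero / max(rho, 1e-12)
        homog = diffusion if j == 0 else 0.0
        stack[j] = homogeneity * homog + (1.0 - homogeneity) * hetero
    return stack


def make_coupling(P, density, order, radius, base=None, divergence=0.0, seed=0,
                  homogeneity=0.7):
    """Draw a stable VAR coupling stack on a sparse symmetric support.

    Off-diagonal support is drawn symmetrically at the requested density and
    diagonal self-couplings are always present. Each lag-1 draw mixes a
    homogeneous diffusion term along the graph (weight ``homogeneity``) with
    heterogeneous per-edge weights, emulating the diffuse spatial
    autocorrelation that makes a connectome prior informative; higher-lag
    matrices are purely heterogeneous. Coefficients are rescaled so the
    VAR(order) companion-matrix spectral radius equals ``radius`` exactly.
    When ``base`` is given, the returned stack is
    ``(1 - divergence) * base + divergence * fresh`` (fresh drawn on the
    base's own support) rescaled back to ``radius``; ``divergence=0`` returns
    the base rescaled with its support unchanged.

    Returns ``(couplings, support)`` with shapes ``(order, P, P)`` and
    ``(P, P)``.
    """
    if P < 2:
        raise InvalidConfigError("P must be >= 2")
    if not 0.0 < radius < 1.0:
        raise InvalidConfigError("radius must lie in (0, 1)")
    if base is not None:
        base = np.asarray(base, dtype=float)
        if base.shape != (order, P, P):
            raise InvalidConfigError(
                f"base shape {base.shape} does not match (order, P, P)={(order, P, P)}")

    for attempt in range(100):
        rng = np.random.default_rng(seed + attempt)
        if base is None:
            support = _draw_support(P, density, rng)
        else:
            off = (base != 0).any(axis=0)
            np.fill_diagonal(off, False)
            support = off.astype(np.uint8)
        try:
            if base is not None and divergence == 0.0:
                couplings = _rescale_to_radius(base, radius)
            else:
                fresh = _draw_stack(P, order, support, homogeneity, rng)
                mix = fresh if base is None else (1.0 - divergence) * base + divergence * fresh
                couplings = _rescale_to_radius(mix, radius)
            if not np.all(np.isfinite(couplings)):
                raise FloatingPointError("non-finite couplings after rescaling")
        except FloatingPointError:
            continue
        return couplings, support
    raise FloatingPointError("could not draw a non-degenerate coupling stack in 100 attempts")


def make_shared_response(T, P, amplitude, cutoff_hz, tr, seed=0):
    """Low-frequency stimulus-evoked component, identical across subjects.

    Each column is white noise low-passed at ``cutoff_hz`` (frequencies above
    the cutoff are removed in the Fourier domain), standardized to zero mean
    and unit population SD, then scaled to ``amplitude``. ``amplitude=0``
    returns the all-zero matrix (a rest-like condition).
    """
    if T < 2:
        raise InvalidConfigError("T must be >= 2")
    if amplitude < 0:
        raise InvalidConfigError("amplitude must be >= 0")
    nyquist = 1.0 / (2.0 * tr)
    if cutoff_hz >= nyquist:
        raise InvalidConfigError(
            f"cutoff_hz={cutoff_hz} must be below the Nyquist frequency {nyquist:.4g}")
    if amplitude == 0.0:
        return np.zeros((T, P))

    freqs = np.fft.rfftfreq(T, d=tr)
    keep = freqs <= cutoff_hz
    if keep.sum() < 2:  # only the DC bin survives -> constant columns
        raise InvalidConfigError(
            "cutoff_hz too low: no non-constant frequency bin below the cutoff")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((T, P))
    spectrum = np.fft.rfft(white, axis=0)
    spectrum[~keep] = 0.0
    smooth = np.fft.irfft(spectrum, n=T, axis=0)
    smooth -= smooth.mean(axis=0)
    sd = smooth.std(axis=0)
    if np.any(sd == 0):
        raise InvalidConfigError("degenerate shared-response draw (zero-variance column)")
    return amplitude * smooth / sd


def simulate_run(couplings, shared, noise_sd, T, burn_in=200, seed=0,
                 subject="sub-01", run="run-00", condition="movie", tr=1.49):
    """Simulate one run of the VAR recursion with a shared evoked component.

    The recursion starts from zero, runs ``burn_in`` extra initial steps that
    are discarded (the shared component is only added to the ``T`` retained
    steps), and returns exactly ``T`` points. Innovations are i.i.d. normal
    with standard deviation ``noise_sd``.
    """
    couplings = np.asarray(couplings, dtype=float)
    order, P, _ = couplings.shape
    if burn_in < order:
        raise InvalidConfigError("burn_in must be >= coupling order")
    if shared is None:
        shared = np.zeros((T, P))
    shared = np.asarray(shared, dtype=float)
    if shared.shape != (T, P):
        raise InvalidConfigError(f"shared shape {shared.shape} != (T, P)={(T, P)}")

    rng = np.random.default_rng(seed)
    total = burn_in + T
    x = np.zeros((total + order, P))
    noise = noise_sd * rng.standard_normal((total, P)) if noise_sd > 0 else np.zeros((total, P))
    for t in range(total):
        acc = noise[t].copy()
        for j in range(order):
            acc += couplings[j] @ x[t + order - 1 - j]
        if t >= burn_in:
            acc += shared[t - burn_in]
        if not np.all(np.isfinite(acc)):
            raise ExplosionError(t)
        x[t + order] = acc
    return ParcelTimeSeries(subject=subject, run=run, condition=condition,
                            data=x[order + burn_in:], tr=tr)


def parcel_coordinates(P, seed=0):
    """Synthetic parcel centroids: P pairwise-distinct points in the unit cube."""
    if P < 2:
        raise InvalidConfigError("P must be >= 2")
    rng = np.random.default_rng(seed)
    for _ in range(100):
        coords = rng.random((P, 3))
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt((diff ** 2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        if dist.min() > 0:
            return coords
    raise FloatingPointError("failed to draw pairwise-distinct coordinates")


def _subseed(base_seed: int, *indices: int) -> int:
    """Deterministic sub-seed derivation, kept below 2**31."""
    s = int(base_seed) % (2 ** 31)
    for ix in indices:
        s = (s * 1_000_003 + int(ix) + 1) % (2 ** 31)
    return s


def generate_cohort(config: CohortConfig):
    """Generate all runs of a cohort plus its ground truth.

    For every (condition, run index) one run is produced per subject; the
    shared component within a (condition, run) pair is identical across
    subjects, and conditions whose label starts with ``"rest"`` get a zero
    shared component. Per-subject couplings are fixed across all runs.
    """
    P, T = config.n_parcels, config.run_length
    base, support = make_coupling(
        P, config.coupling_density, config.coupling_order, config.spectral_radius,
        seed=_subseed(config.seed, 0), homogeneity=config.coupling_homogeneity)
    couplings = np.empty((config.n_subjects, config.coupling_order, P, P))
    for s in range(config.n_subjects):
        couplings[s], _ = make_coupling(
            P, config.coupling_density, config.coupling_order, config.spectral_radius,
            base=base, divergence=config.subject_divergence,
            seed=_subseed(config.seed, 1, s), homogeneity=config.coupling_homogeneity)

    shared_responses = {}
    runs = []
    for ci, (condition, n_runs) in enumerate(sorted(config.n_runs_per_condition.items())):
        amplitude = 0.0 if condition.lower().startswith(REST_PREFIX) else config.shared_amplitude
        for r in range(n_runs):
            shared = make_shared_response(
                T, P, amplitude, config.shared_cutoff_hz, config.tr,
                seed=_subseed(config.seed, 2, ci, r))
            shared_responses[(condition, r)] = shared
            for s in range(config.n_subjects):
                runs.append(simulate_run(
                    couplings[s], shared, config.noise_sd, T,
                    seed=_subseed(config.seed, 3, ci, r, s),
                    subject=f"sub-{s + 1:02d}", run=f"run-{r:02d}",
                    condition=condition, tr=config.tr))

    truth = GroundTruth(
        couplings=couplings,
        support_graph=support,
        shared_responses=shared_responses,
        parcel_coords=parcel_coordinates(P, seed=_subseed(config.seed, 4)),
    )
    return runs, truth


# ---------------------------------------------------------------------------
# on-disk format: one TSV per run + a YAML manifest + an .npz ground truth
# ---------------------------------------------------------------------------

def write_cohort(runs, truth, out_dir, config=None):
    """Write run tables, a cohort manifest and the ground-truth archive."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for ts in runs:
        fname = f"{ts.subject}_{ts.condition}_{ts.run}.tsv"
        labels = [f"parcel-{j:03d}" for j in range(ts.n_parcels)]
        pd.DataFrame(ts.data, columns=labels).to_csv(out / fname, sep="\t", index=False,
                                                     float_format="%.10g")
        entries.append({"subject": ts.subject, "run": ts.run, "condition": ts.condition,
                        "tr": ts.tr, "path": fname})
    manifest = {"tr": runs[0].tr if runs else None,
                "n_parcels": runs[0].n_parcels if runs else None,
                "runs": entries}
    if config is not None:
        cfg = dataclasses.asdict(config)
        cfg["n_runs_per_condition"] = dict(cfg["n_runs_per_condition"])
        manifest["config"] = cfg
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    if truth is not None:
        shared_keys = sorted(truth.shared_responses)
        np.savez(out / "ground_truth.npz",
                 couplings=truth.couplings,
                 support_graph=truth.support_graph,
                 parcel_coords=truth.parcel_coords,
                 shared_keys=json.dumps([[c, r] for c, r in shared_keys]),
                 **{f"shared_{i}": truth.shared_responses[k]
                    for i, k in enumerate(shared_keys)})
    return out


def read_cohort(in_dir):
    """Read back a cohort written by :func:`write_cohort`.

    Returns ``(runs, truth_or_None)``.
    """
    src = Path(in_dir)
    manifest = yaml.safe_load((src / "manifest.yaml").read_text())
    runs = []
    for entry in manifest["runs"]:
        table = pd.read_csv(src / entry["path"], sep="\t")
        runs.append(ParcelTimeSeries(subject=entry["subject"], run=entry["run"],
                                     condition=entry["condition"], data=table.to_numpy(),
                                     tr=entry["tr"]))
    truth = None
    gt_path = src / "ground_truth.npz"
    if gt_path.exists():
        with np.load(gt_path, allow_pickle=False) as z:
            keys = [(c, int(r)) for c, r in json.loads(str(z["shared_keys"]))]
            truth = GroundTruth(
                couplings=z["couplings"],
                support_graph=z["support_graph"],
                shared_responses={k: z[f"shared_{i}"] for i, k in enumerate(keys)},
                parcel_coords=z["parcel_coords"],
            )
    return runs, truth
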