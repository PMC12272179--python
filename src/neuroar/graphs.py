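"""Binary parcel graphs (functional, spatial, random) at fixed edge density,
and the scaled graph Laplacian used by Chebyshev spectral filters."""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError, InvalidConfigError

__all__ = [
    "Connectome",
    "SpectralOperator",
    "functional_connectome",
    "binarize_top_density",
    "spatial_connectome",
    "random_connectome",
    "scaled_laplacian",
]


@dataclasses.dataclass(frozen=True)
class Connectome:
    adjacency: np.ndarray  # (P, P) binary symmetric, zero diagonal
    density: float         # achieved fraction of off-diagonal pairs connected
    kind: str              # "functional" | "spatial" | "random"

    def __post_init__(self):
        A = np.asarray(self.adjacency)
        if not np.array_equal(A, A.T) or np.any(np.diag(A) != 0):
            raise InvalidConfigError("adjacency must be symmetric with a zero diagonal")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclasses.dataclass(frozen=True)
class SpectralOperator:
    """Scaled Laplacian L~ = (2 / lambda_max) L - I with spectrum in [-1, 1]."""

    scaled_laplacian: np.ndarray
    lambda_max: float


def _edge_budget(P: int, density: float) -> int:
    if not 0.0 < density <= 1.0:
        raise InvalidConfigError("density must lie in (0, 1]")
    return int(round(density * P * (P - 1) / 2))


def _from_pairs(P: int, rows, cols, m: int, kind: str) -> Connectome:
    A = np.zeros((P, P), dtype=np.uint8)
    A[rows, cols] = 1
    A |= A.T
    return Connectome(adjacency=A, density=m / (P * (P - 1) / 2), kind=kind)


def functional_connectome(train_runs: Sequence) -> np.ndarray:
    """Pearson correlation between parcels over the time-concatenated training runs."""
    data = np.concatenate([ts.data for ts in train_runs], axis=0)
    if data.shape[0] < 2:
        raise InvalidConfigError("need at least 2 total time points")
    sd = data.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise DegenerateInputError(f"constant parcel(s) {constant.tolist()}: "
                                   "correlation undefined")
    return np.corrcoef(data, rowvar=False)


def binarize_top_density(weights: np.ndarray, density: float, kind: str = "functional",
                         absolute: bool = False) -> Connectome:
    """Keep the top-density fraction of off-diagonal pairs by (signed) weight.

    ``m = round(density * P(P-1)/2)`` pairs with the highest weight receive an
    edge. Ties crossing the m-th rank are broken by (row, col) lexicographic
    order of the pair (a warning is logged). ``absolute=True`` ranks by
    absolute weight instead of signed weight.
    """
    W = np.asarray(weights, dtype=float)
    P = W.shape[0]
    if not np.allclose(W, W.T):
        raise InvalidConfigError("weights must be symmetric")
    m = _edge_budget(P, density)
    iu = np.triu_indices(P, k=1)
    vals = np.abs(W[iu]) if absolute else W[iu]
    # stable sort on descending value; triu_indices is already lexicographic
    order = np.argsort(-vals, kind="stable")
    if 0 < m < vals.size and vals[order[m - 1]] == vals[order[m]]:
        warnings.warn("ties cross the selection boundary; broken lexicographically",
                      stacklevel=2)
    sel = order[:m]
    return _from_pairs(P, iu[0][sel], iu[1][sel], m, kind)


def spatial_connectome(coords: np.ndarray, density: float) -> Connectome:
    """Edges between the m spatially closest parcel pairs (Euclidean distance)."""
    coords = np.asarray(coords, dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    off = dist[np.triu_indices(len(coords), k=1)]
    if np.any(off == 0):
        raise InvalidConfigError("duplicate coordinates: spatial graph undefined")
    return binarize_top_density(-dist, density, kind="spatial")


def random_connectome(P: int, density: float, seed: int = 0) -> Connectome:
    """Exactly m edges sampled uniformly without replacement, seeded."""
    m = _edge_budget(P, density)
    n_pairs = P * (P - 1) // 2
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_pairs, size=m, replace=False)
    iu = np.triu_indices(P, k=1)
    return _from_pairs(P, iu[0][chosen], iu[1][chosen], m, "random")


def scaled_laplacian(connectome: Connectome) -> SpectralOperator:
    """Symmetric normalized Laplacian, rescaled into Chebyshev domain [-1, 1].

    L = I - D^{-1/2} A D^{-1/2}, with the D^{-1/2} entry of an isolated node
    defined as 0 (its L row is then an identity row); lambda_max is the
    largest eigenvalue of L and L~ = (2 / lambda_max) L - I. An edgeless
    graph has lambda_max = 0; the conventional fallback lambda_max = 2 is
    used (with a warning), giving L~ = L - I.
    """
    A = connectome.adjacency.astype(float)
    P = A.shape[0]
    deg = A.sum(axis=1)
    with np.errstate(divide="ignore"):
        d_inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
    L = np.eye(P) - d_inv_sqrt[:, None] * A * d_inv_sqrt[None, :]
    if connectome.n_edges == 0:
        warnings.warn("edgeless graph: using the lambda_max = 2 convention", stacklevel=2)
        lam = 2.0
    else:
        lam = float(np.linalg.eigvalsh(L).max())
    Lt = (2.0 / lam) * L - np.eye(P)
    return SpectralOperator(scaled_laplacian=Lt, lambda_max=lam)


def write_connectome(connectome: Connectome, path) -> None:
    """Write the adjacency as a delimited 0/1 table with a JSON metadata sidecar."""
    import json
    from pathlib import Path
    path = Path(path)
    np.savetxt(path, connectome.adjacency, fmt="%d", delimiter="\t")
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(
        {"kind": connectome.kind, "density": connectome.density,
         "n_nodes": connectome.n_nodes, "n_edges": connectome.n_edges}))


def read_connectome(path) -> Connectome:
    """Read a connectome written by :func:`write_connectome`."""
    import json
    from pathlib import Path
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    adjacency = np.loadtxt(path, dtype=np.uint8, delimiter="\t")
    return Connectome(adjacency=adjacency, density=meta["density"], kind=meta["kind"])
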