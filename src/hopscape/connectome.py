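"""Structural connectivity matrices: loading, normalization, degree-preserving
randomization, and synthetic modular graph generation.

A :class:`Connectome` wraps a square, symmetric, non-negative weight matrix
together with node labels and optional hemisphere tags.  All downstream
dynamics assume unit-norm coupling; :func:`normalize` produces that form under
a configurable matrix norm (Frobenius by default).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: absolute tolerance for the symmetry check
SYMMETRY_TOL = 1e-12
#: tolerance on ||W|| == 1 for matrices flagged as normalized
NORM_TOL = 1e-9

NORMS = ("frobenius", "spectral", "max_row_sum")


class ConnectomeError(ValueError):
    """Base class for connectivity-matrix validation errors."""


class NonSquareMatrixError(ConnectomeError):
    """Input matrix is not square."""


class AsymmetricMatrixError(ConnectomeError):
    """Input matrix is not symmetric within tolerance."""


class NegativeWeightError(ConnectomeError):
    """Input matrix contains negative entries."""


class SidecarMismatchError(ConnectomeError):
    """Sidecar label/hemisphere arrays do not match the matrix size."""


class ZeroMatrixError(ConnectomeError):
    """Matrix has no non-zero entry and cannot be normalized."""


class SelfCouplingError(ConnectomeError):
    """Non-zero diagonal without allow_self_coupling."""


def matrix_norm(weights: np.ndarray, norm: str) -> float:
    """Evaluate one of the supported matrix norms."""
    if norm == "frobenius":
        return float(np.linalg.norm(weights, "fro"))
    if norm == "spectral":
        # symmetric matrix: spectral norm is the largest absolute eigenvalue
        return float(np.max(np.abs(np.linalg.eigvalsh(weights))))
    if norm == "max_row_sum":
        return float(np.max(np.sum(np.abs(weights), axis=1)))
    raise ValueError(f"unknown norm {norm!r}; expected one of {NORMS}")


@dataclass(frozen=True)
class Connectome:
    """A symmetric, non-negative weighted connectivity matrix.

    Parameters
    ----------
    weights
        N x N array of non-negative coupling weights.
    labels
        Node identifiers; defaults to ``node0000 ...``.
    hemisphere
        Optional per-node tags (``"L"``, ``"R"`` or other strings).
    normalized
        True when the matrix has been rescaled to unit norm.
    norm
        Name of the norm used for normalization (when ``normalized``).
    allow_self_coupling
        Permit non-zero diagonal entries (needed for single-node
        analytic configurations); empirical connectomes keep a zero
        diagonal.
    """

    weights: np.ndarray
    labels: tuple = None
    hemisphere: tuple = None
    normalized: bool = False
    norm: str = None
    allow_self_coupling: bool = False

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise NonSquareMatrixError(f"matrix of shape {w.shape} is not square")
        if not np.all(np.isfinite(w)):
            raise ConnectomeError("matrix contains non-finite entries")
        if np.max(np.abs(w - w.T), initial=0.0) > SYMMETRY_TOL:
            raise AsymmetricMatrixError(
                "matrix is not symmetric within tolerance "
                f"{SYMMETRY_TOL}; refusing to symmetrize silently"
            )
        if np.any(w < 0):
            i, j = np.argwhere(w < 0)[0]
            raise NegativeWeightError(f"negative weight at ({i}, {j})")
        if not self.allow_self_coupling and np.any(np.diag(w) != 0):
            i = int(np.argwhere(np.diag(w) != 0)[0])
            raise SelfCouplingError(
                f"non-zero diagonal entry at node {i}; pass "
                "allow_self_coupling=True to permit self-loops"
            )
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)
        n = w.shape[0]
        if self.labels is None:
            object.__setattr__(self, "labels", tuple(f"node{i:04d}" for i in range(n)))
        else:
            labels = tuple(str(x) for x in self.labels)
            if len(labels) != n:
                raise SidecarMismatchError(
                    f"{len(labels)} labels for {n} nodes"
                )
            object.__setattr__(self, "labels", labels)
        if self.hemisphere is not None:
            hemi = tuple(str(x) for x in self.hemisphere)
            if len(hemi) != n:
                raise SidecarMismatchError(
                    f"{len(hemi)} hemisphere tags for {n} nodes"
                )
            object.__setattr__(self, "hemisphere", hemi)
        if self.normalized:
            norm = self.norm or "frobenius"
            value = matrix_norm(w, norm)
            if abs(value - 1.0) > NORM_TOL:
                raise ConnectomeError(
                    f"normalized flag set but ||W||_{norm} = {value!r}"
                )

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def row_sums(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    def lambda_max(self) -> float:
        """Largest eigenvalue (symmetric matrix)."""
        return float(np.linalg.eigvalsh(self.weights)[-1])


def load_connectome(path, sidecar=None, allow_self_coupling: bool = False) -> Connectome:
    """Load a whitespace-delimited square matrix, optionally with a JSON sidecar.

    The sidecar is an object with a ``"labels"`` array and an optional
    ``"hemisphere"`` array of matching length.  Asymmetric input is
    rejected, never symmetrized.
    """
    w = np.loadtxt(path, ndmin=2)
    labels = hemisphere = None
    if sidecar is not None:
        with open(sidecar) as fh:
            meta = json.load(fh)
        labels = meta.get("labels")
        hemisphere = meta.get("hemisphere")
    return Connectome(
        w,
        labels=labels,
        hemisphere=hemisphere,
        normalized=False,
        allow_self_coupling=allow_self_coupling,
    )


def save_connectome(c: Connectome, path, sidecar=None) -> None:
    """Write the weight matrix as TSV, and labels/hemisphere as JSON."""
    np.savetxt(path, c.weights, delimiter="\t", fmt="%.17g")
    if sidecar is not None:
        meta = {"labels": list(c.labels)}
        if c.hemisphere is not None:
            meta["hemisphere"] = list(c.hemisphere)
        Path(sidecar).write_text(json.dumps(meta, indent=1))


def normalize(c: Connectome, norm: str = "frobenius") -> Connectome:
    """Rescale weights to unit matrix norm.

    Raises :class:`ZeroMatrixError` on an all-zero matrix.
    """
    value = matrix_norm(c.weights, norm)
    if value == 0.0:
        raise ZeroMatrixError("all-zero matrix cannot be normalized")
    return replace(c, weights=c.weights / value, normalized=True, norm=norm)


def maslov_sneppen_randomize(
    c: Connectome,
    n_swaps: int,
    seed: int,
    attempt_cap: int = None,
) -> Connectome:
    """Degree-preserving random rewiring of the non-null edges.

    A proposal picks two undirected edges (a-b, c-d) and rewires them to
    (a-d, c-b), accepted only when all four nodes are distinct and
    neither target edge already exists.  Weights travel with their
    original source node: w(a,d) <- w(a,b) and w(c,b) <- w(c,d).
    Rejected proposals are retried up to ``attempt_cap`` total attempts
    (default ``100 * n_swaps``); if no valid swap can be realised the
    input is returned unchanged with a logged warning.

    Preserved exactly: node count, edge count, per-node degree, the
    multiset of edge weights, symmetry.
    """
    if n_swaps < 1:
        raise ValueError("n_swaps must be >= 1")
    if attempt_cap is None:
        attempt_cap = 100 * n_swaps
    rng = np.random.default_rng(seed)
    w = np.array(c.weights, dtype=float)
    n = w.shape[0]
    iu, ju = np.nonzero(np.triu(w, k=1))
    edges = [[int(a), int(b)] for a, b in zip(iu, ju)]
    adj = w > 0
    if len(edges) < 2:
        logger.warning("fewer than two edges; returning connectome unchanged")
        return c

    done = attempts = 0
    while done < n_swaps and attempts < attempt_cap:
        attempts += 1
        e1, e2 = rng.choice(len(edges), size=2, replace=False)
        a, b = edges[e1]
        c_, d = edges[e2]
        if rng.random() < 0.5:
            c_, d = d, c_
        if len({a, b, c_, d}) < 4:
            continue
        if adj[a, d] or adj[c_, b]:
            continue
        wab, wcd = w[a, b], w[c_, d]
        w[a, b] = w[b, a] = 0.0
        w[c_, d] = w[d, c_] = 0.0
        w[a, d] = w[d, a] = wab
        w[c_, b] = w[b, c_] = wcd
        adj[a, b] = adj[b, a] = adj[c_, d] = adj[d, c_] = False
        adj[a, d] = adj[d, a] = adj[c_, b] = adj[b, c_] = True
        edges[e1] = [a, d]
        edges[e2] = [c_, b]
        done += 1

    if done == 0:
        logger.warning(
            "no valid degree-preserving swap found after %d attempts; "
            "returning connectome unchanged",
            attempts,
        )
        return c
    if done < n_swaps:
        logger.warning(
            "only %d of %d requested swaps realised within the attempt cap",
            done,
            n_swaps,
        )
    return replace(c, weights=w, normalized=False, norm=None)


def synthetic_connectome(
    n: int,
    n_modules: int = 4,
    p_intra: float = 0.3,
    p_inter: float = 0.02,
    weight_law: str = "lognormal",
    seed: int = 0,
) -> Connectome:
    """Generate a sparse, symmetric, modular, positively weighted graph.

    Nodes are split into ``n_modules`` contiguous blocks; within-block
    pairs connect with probability ``p_intra`` and cross-block pairs with
    ``p_inter``.  Each module is split half/half into L and R hemisphere
    tags.  Fully reproducible under a fixed seed.
    """
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if not (0.0 <= p_inter <= p_intra <= 1.0):
        raise ValueError("require 0 <= p_inter <= p_intra <= 1")
    if weight_law not in ("uniform", "lognormal"):
        raise ValueError(f"unknown weight_law {weight_law!r}")
    rng = np.random.default_rng(seed)
    module = np.floor(np.arange(n) * n_modules / n).astype(int)
    same = module[:, None] == module[None, :]
    p = np.where(same, p_intra, p_inter)
    mask = np.triu(rng.random((n, n)) < p, k=1)
    if weight_law == "uniform":
        vals = rng.uniform(0.0, 1.0, size=(n, n))
    else:
        vals = rng.lognormal(mean=0.0, sigma=1.0, size=(n, n))
    w = np.where(mask, vals, 0.0)
    w = w + w.T
    hemi = []
    for m in module:
        idx_in_module = np.sum(module[: len(hemi)] == m)
        size = np.sum(module == m)
        hemi.append("L" if idx_in_module < size / 2 else "R")
    return Connectome(w, hemisphere=tuple(hemi))
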