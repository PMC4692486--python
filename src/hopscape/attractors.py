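"""Sampling-based reconstruction of the attractor landscape, plus its
energy / probability / entropy characterization and parameter sweeps.

The search protocol relaxes batches of random binary initial patterns at a
grid of initial densities, stops each run at equilibrium (or after a 1 s
cap), and deduplicates the final output patterns with a double
dissimilarity rule: a pattern counts as a *new* attractor only when both
its Pearson correlation and its Euclidean similarity to every stored
attractor are below 0.9; otherwise the best-matching stored attractor's
cardinality is incremented.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import dynamics
from .dynamics import ModelConfig, activation, relax, static_thresholds

logger = logging.getLogger(__name__)

#: both similarities must fall below this for a pattern to be stored as new
DEDUP_THRESHOLD = 0.9
#: variance below this is treated as zero when correlating patterns
VAR_FLOOR = 1e-24

DEFAULT_DENSITY_GRID = np.round(np.arange(0.02, 0.981, 0.03), 10)


def pearson_similarity(x, y) -> float:
    """Pearson correlation; defined as 0 (with a warning) for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx, vy = x.var(), y.var()
    if vx < VAR_FLOOR or vy < VAR_FLOOR:
        warnings.warn("zero-variance pattern in Pearson similarity; returning 0")
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def euclidean_similarity(x, y) -> float:
    """1 / (1 + Euclidean distance), in (0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(1.0 / (1.0 + np.linalg.norm(x - y)))


@dataclass
class Attractor:
    """A relaxed output pattern with basin statistics."""

    pattern: np.ndarray             # final outputs A in [0,1]^N
    potentials: Optional[np.ndarray] = None  # final potentials x
    cardinality: int = 1
    lyapunov: Optional[float] = None
    energy: Optional[float] = None

    @property
    def density(self) -> float:
        return float(np.mean(self.pattern))


@dataclass
class AttractorSet:
    """Deduplicated set of attractors plus search provenance.

    The stored patterns are pairwise dissimilar under the double
    dissimilarity rule, and the cardinalities sum to the number of
    equilibrated samples absorbed.
    """

    n_nodes: int
    attractors: list = field(default_factory=list)
    n_samples: int = 0
    n_equilibrated: int = 0
    provenance: dict = field(default_factory=dict)
    # stacked pattern matrix kept in sync for vectorized similarity tests
    _patterns: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return len(self.attractors)

    def patterns(self) -> np.ndarray:
        if not self.attractors:
            return np.empty((0, self.n_nodes))
        return np.vstack([a.pattern for a in self.attractors])

    def cardinalities(self) -> np.ndarray:
        return np.array([a.cardinality for a in self.attractors], dtype=int)

    def densities(self) -> np.ndarray:
        return np.array([a.density for a in self.attractors])

    def _similarities(self, pattern: np.ndarray):
        """Pearson and Euclidean similarity of ``pattern`` vs every stored one."""
        P = self._patterns
        d = P - pattern[None, :]
        eucl = 1.0 / (1.0 + np.sqrt(np.einsum("ij,ij->i", d, d)))
        pc = P - P.mean(axis=1, keepdims=True)
        xc = pattern - pattern.mean()
        denom = np.sqrt(np.einsum("ij,ij->i", pc, pc) * (xc @ xc))
        with np.errstate(invalid="ignore", divide="ignore"):
            pear = np.where(denom > np.sqrt(VAR_FLOOR), (pc @ xc) / denom, 0.0)
        return pear, eucl


def absorb_or_add(pattern: np.ndarray, aset: AttractorSet,
                  potentials: Optional[np.ndarray] = None):
    """Store ``pattern`` as a new attractor, or absorb it into the best match.

    New iff (pearson < 0.9) and (euclidean similarity < 0.9) against every
    stored attractor; otherwise the cardinality of the stored attractor
    maximizing max(pearson, euclidean) is incremented (ties: lowest index).
    Returns ``(index, is_new)``.
    """
    pattern = np.asarray(pattern, dtype=float)
    aset.n_equilibrated += 1
    if not aset.attractors:
        aset.attractors.append(Attractor(pattern=pattern, potentials=potentials))
        aset._patterns = pattern[None, :].copy()
        return 0, True
    pear, eucl = aset._similarities(pattern)
    novel = np.all((pear < DEDUP_THRESHOLD) & (eucl < DEDUP_THRESHOLD))
    if novel:
        aset.attractors.append(Attractor(pattern=pattern, potentials=potentials))
        aset._patterns = np.vstack([aset._patterns, pattern])
        return len(aset.attractors) - 1, True
    best = int(np.argmax(np.maximum(pear, eucl)))
    aset.attractors[best].cardinality += 1
    return best, False


def sample_attractors(
    w,
    cfg: ModelConfig,
    density_grid: Optional[np.ndarray] = None,
    n_per_density: int = 100,
    seed: int = 0,
    t_max: float = dynamics.RELAX_CAP,
) -> AttractorSet:
    """Random sampling-based attractor search.

    For each density in the grid, ``n_per_density`` random binary patterns
    are relaxed deterministically (DG runs use tau_theta = tau_x), stopping
    at equilibrium or after the 1 s cap.  Equilibrated final output
    patterns are deduplicated into the returned :class:`AttractorSet`;
    non-equilibrated runs are counted but excluded.  Per-density attractor
    counts (deduplicated with the same rule, per density) are stored in
    ``provenance["per_density"]``.
    """
    if density_grid is None:
        density_grid = DEFAULT_DENSITY_GRID
    density_grid = np.asarray(density_grid, dtype=float)
    if cfg.variant == "DG" and cfg.tau_theta != cfg.tau_x:
        cfg = ModelConfig(**{**cfg.__dict__, "tau_theta": cfg.tau_x})
    n = w.weights.shape[0]
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = root.spawn(len(density_grid))
    aset = AttractorSet(n_nodes=n)
    per_density = []
    n_failed = 0
    for f0, ss in zip(density_grid, seeds):
        rng = np.random.default_rng(ss)
        X0 = (rng.random((n_per_density, n)) < f0).astype(float)
        Xf, Tf, ok, _ = relax(w, cfg, X0, t_max=t_max)
        theta = Tf if cfg.variant == "SL" else np.asarray(Tf)[:, None]
        Af = activation(Xf, theta, cfg.G, cfg.P)
        local = AttractorSet(n_nodes=n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(n_per_density):
                aset.n_samples += 1
                if not ok[i]:
                    n_failed += 1
                    continue
                absorb_or_add(Af[i], aset, potentials=Xf[i])
                absorb_or_add(Af[i], local)
        per_density.append({
            "f0": float(f0),
            "n_attractors": len(local),
            "n_equilibrated": int(ok.sum()),
            "mean_final_density": float(np.mean(Af[ok])) if ok.any() else np.nan,
        })
    aset.provenance = {
        "config": cfg.__dict__.copy(),
        "density_grid": density_grid.tolist(),
        "n_per_density": int(n_per_density),
        "seed": repr(seed),
        "n_non_equilibrated": int(n_failed),
        "per_density": pd.DataFrame(per_density),
    }
    return aset


def lyapunov_value(x, w, cfg: ModelConfig, theta=None) -> float:
    """Potential-function value at ``x`` for static-threshold configurations.

    V(x) = 1/2 sum_i [ x_i^2 - x_i sum_j W_ij
                       - x_i sum_{j != i} W_ij tanh(G (P x_j - theta_j))
                       - W_ii / (G P) ln cosh(G (P x_i - theta_i)) ]

    The ln-cosh self-coupling term vanishes for zero-diagonal matrices.
    """
    if cfg.variant == "DG":
        raise ValueError("potential function is defined for static thresholds (SL/SG)")
    W = w.weights if hasattr(w, "weights") else np.asarray(w)
    x = np.asarray(x, dtype=float)
    if theta is None:
        theta = static_thresholds(W, cfg.variant)
    theta = np.broadcast_to(np.asarray(theta, dtype=float), x.shape)
    z = cfg.G * (cfg.P * x - theta)
    t = np.tanh(z)
    diag = np.diag(W)
    rowsum = W.sum(axis=1)
    cross = W @ t - diag * t  # sum over j != i
    az = np.abs(z)
    lncosh = az + np.log1p(np.exp(-2.0 * az)) - np.log(2.0)
    terms = x * x - x * rowsum - x * cross - diag * lncosh / (cfg.G * cfg.P)
    return float(0.5 * np.sum(terms))


def ising_energy(a, w, theta) -> float:
    """Ising energy of a binary pattern: -1/2 a'Wa - theta . a."""
    W = w.weights if hasattr(w, "weights") else np.asarray(w)
    a = np.asarray(a, dtype=float)
    theta = np.broadcast_to(np.asarray(theta, dtype=float), a.shape)
    return float(-0.5 * a @ W @ a - theta @ a)


def boltzmann_distribution(energies, beta: float) -> np.ndarray:
    """Boltzmann-Gibbs probabilities exp(-beta E) / Z, max-shifted."""
    E = np.asarray(energies, dtype=float)
    if E.size == 0:
        raise ValueError("empty energy vector")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    z = -beta * E
    z = z - z.max()
    p = np.exp(z)
    return p / p.sum()


def boltzmann_entropy(energies, beta: float, base: float = np.e) -> float:
    """Entropy of the Boltzmann distribution, sum(beta E p) + log Z form."""
    E = np.asarray(energies, dtype=float)
    logZ = logsumexp(-beta * E)
    p = boltzmann_distribution(E, beta)
    H = float(beta * np.sum(E * p) + logZ)
    return H / np.log(base)


def empirical_entropy(cardinalities, base: float = 2.0) -> float:
    """Shannon entropy of the cardinality distribution (bits by default)."""
    c = np.asarray(cardinalities, dtype=float)
    if c.size == 0 or np.any(c <= 0):
        raise ValueError("cardinalities must be a non-empty vector of positives")
    p = c / c.sum()
    return float(-np.sum(p * np.log(p)) / np.log(base))


def sweep_gain(
    w,
    cfg: ModelConfig,
    G_values,
    n_per_density: int = 100,
    seed: int = 0,
    density_grid: Optional[np.ndarray] = None,
    with_lyapunov: bool = False,
):
    """Attractor search repeated over a grid of gains.

    Returns ``(table, sets)`` where ``table`` has one row per gain with the
    attractor count, mean attractor density and empirical entropy, and
    ``sets`` maps each gain to its :class:`AttractorSet`.
    """
    G_values = np.asarray(G_values, dtype=float)
    if G_values.size == 0:
        raise ValueError("empty gain grid")
    seeds = np.random.SeedSequence(seed).spawn(len(G_values))
    rows, sets = [], {}
    for G, ss in zip(G_values, seeds):
        cfg_g = ModelConfig(**{**cfg.__dict__, "G": float(G)})
        aset = sample_attractors(
            w, cfg_g, density_grid=density_grid,
            n_per_density=n_per_density, seed=ss,
        )
        if with_lyapunov and cfg.variant != "DG":
            for a in aset.attractors:
                a.lyapunov = lyapunov_value(a.potentials, w, cfg_g)
        rows.append({
            "G": float(G),
            "n_attractors": len(aset),
            "mean_density": float(aset.densities().mean()) if len(aset) else np.nan,
            "entropy_bits": empirical_entropy(aset.cardinalities()) if len(aset) else np.nan,
            "n_equilibrated": aset.n_equilibrated,
        })
        sets[float(G)] = aset
        logger.info("gain sweep: G=%g -> %d attractors", G, len(aset))
    return pd.DataFrame(rows), sets


def sweep_P_density(
    w,
    cfg: ModelConfig,
    P_values,
    f0_values,
    n_per_cell: int = 100,
    seed: int = 0,
):
    """Attractor search over a (P, f0) grid, one cell per pair.

    Each cell relaxes ``n_per_cell`` samples at a single initial density.
    Returns a long-format table with one row per cell: attractor count,
    mean final attractor density, empirical entropy, equilibrated count.
    """
    P_values = np.asarray(P_values, dtype=float)
    f0_values = np.asarray(f0_values, dtype=float)
    ss = np.random.SeedSequence(seed).spawn(len(P_values) * len(f0_values))
    rows = []
    k = 0
    for P in P_values:
        cfg_p = ModelConfig(**{**cfg.__dict__, "P": float(P)})
        for f0 in f0_values:
            aset = sample_attractors(
                w, cfg_p, density_grid=[float(f0)],
                n_per_density=n_per_cell, seed=ss[k],
            )
            k += 1
            dens = aset.densities()
            cards = aset.cardinalities()
            mean_density = (
                float(np.average(dens, weights=cards)) if len(aset) else np.nan
            )
            rows.append({
                "P": float(P),
                "f0": float(f0),
                "n_attractors": len(aset),
                "mean_final_density": mean_density,
                "entropy_bits": empirical_entropy(cards) if len(aset) else np.nan,
                "n_equilibrated": aset.n_equilibrated,
            })
    return pd.DataFrame(rows)


def detect_first_bifurcation(
    w,
    cfg: ModelConfig,
    G_values,
    perturbation: float = 2e-3,
    horizon: float = 1500.0,
    threshold: float = 1e-2,
):
    """Smallest gain at which the central equilibrium loses stability.

    Valid for the SL model at P = 1, where x_c = (row sums)/2 is an exact
    equilibrium for every gain and loses stability at G_c = 2/lambda_max(W).
    For each gain (ascending) the central state is perturbed by +/-
    ``perturbation`` along the leading eigenvector and integrated for
    ``horizon`` ms without early stopping; the gain is flagged bifurcated
    when either final state deviates from the central state by more than
    ``threshold`` (max norm).  Returns the first such gain, or None.
    """
    W = w.weights if hasattr(w, "weights") else np.asarray(w)
    x_c = 0.5 * W.sum(axis=1)
    evals, evecs = np.linalg.eigh(W)
    v = evecs[:, -1]
    v = v / np.max(np.abs(v))
    for G in np.sort(np.asarray(G_values, dtype=float)):
        cfg_g = ModelConfig(**{**cfg.__dict__, "G": float(G)})
        X0 = np.vstack([x_c + perturbation * v, x_c - perturbation * v])
        Xf, _, _, _ = relax(
            w, cfg_g, X0, t_max=horizon, stop_at_equilibrium=False,
        )
        dev = np.max(np.abs(Xf - x_c[None, :]), axis=1)
        if np.any(dev > threshold):
            return float(G)
    return None
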