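"""Deterministic and stochastic time integration of the three graded-response
network variants.

Variants differ only in their activation threshold:

``SL``
    static local thresholds, one per node (half the node's row sum);
``SG``
    a single static threshold (mean of the SL vector);
``DG``
    a single dynamic threshold relaxing toward the mean node output.

Integration is explicit Euler (Euler-Maruyama when noise is on) with a
default step of 0.1 ms.  :func:`relax` integrates a whole batch of initial
conditions at once, which is what makes large attractor-sampling sweeps
feasible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

VARIANTS = ("SL", "SG", "DG")

#: default relative tolerance of the equilibrium stop rule
EQ_EPS = 1e-6
#: default averaging window of the equilibrium stop rule (ms)
EQ_WINDOW = 100.0
#: absolute floor guarding the relative equilibrium criterion
EQ_FLOOR = 1e-6
#: hard cap on relaxation time when equilibrium is not reached (ms)
RELAX_CAP = 1000.0


class NonFiniteStateError(FloatingPointError):
    """State became non-finite during integration."""

    def __init__(self, node: int, t: float):
        self.node = int(node)
        self.t = float(t)
        super().__init__(f"non-finite potential at node {node} (t = {t:g} ms)")


@dataclass(frozen=True)
class ModelConfig:
    """All dynamical parameters of one model variant.

    ``noise_scaling`` selects how the written diffusion strengths map to
    discrete increments: ``"tau"`` (default) reads sigma as the diffusion
    strength of the tau-scaled SDE, giving increments (sigma/tau)*sqrt(dt);
    ``"plain"`` drops the 1/tau factor.
    """

    variant: str
    G: float
    P: float = 1.0
    tau_x: float = 10.0
    tau_theta: float = 80.0
    sigma_x: float = 0.0
    sigma_theta: float = 0.0
    dt: float = 0.1
    seed: int = 0
    noise_scaling: str = "tau"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if not (self.G > 0 and self.P >= 0):
            raise ValueError("require G > 0 and P >= 0")
        if not (self.tau_x > 0 and self.tau_theta > 0 and self.dt > 0):
            raise ValueError("time constants and dt must be positive")
        if self.sigma_x < 0 or self.sigma_theta < 0:
            raise ValueError("noise strengths must be non-negative")
        if self.noise_scaling not in ("tau", "plain"):
            raise ValueError("noise_scaling must be 'tau' or 'plain'")

    @property
    def stochastic(self) -> bool:
        return self.sigma_x > 0 or self.sigma_theta > 0

    def _noise_factor(self, tau: float) -> float:
        return 1.0 / tau if self.noise_scaling == "tau" else 1.0


@dataclass
class NetworkState:
    """Node potentials plus threshold state at a point in time."""

    x: np.ndarray
    theta: np.ndarray  # shape (N,) for SL; shape () for SG/DG
    t: float = 0.0

    def copy(self) -> "NetworkState":
        return NetworkState(self.x.copy(), np.array(self.theta, copy=True), self.t)


@dataclass
class Trajectory:
    """Recorded time course of a single simulation."""

    times: np.ndarray          # (T,) ms
    states: np.ndarray         # (T, N) potentials
    thetas: np.ndarray         # (T, N) or (T,) thresholds
    record_stride: int
    config: ModelConfig
    terminated: str = "t_max"  # "t_max" or "equilibrium"

    def outputs(self) -> np.ndarray:
        """Node outputs A for each recorded state."""
        theta = self.thetas
        if theta.ndim == 1 and self.states.ndim == 2:
            theta = theta[:, None]
        return activation(self.states, theta, self.config.G, self.config.P)

    def save_tsv(self, path) -> None:
        """Write time + per-node potential columns as TSV."""
        header = "time_ms\t" + "\t".join(
            f"x{i}" for i in range(self.states.shape[1])
        )
        np.savetxt(
            path,
            np.column_stack([self.times, self.states]),
            delimiter="\t",
            header=header,
            comments="",
            fmt="%.10g",
        )


def activation(x, theta, G: float, P: float) -> np.ndarray:
    """Sigmoid node output in [0, 1]: A = (1 + tanh(G(Px - theta))) / 2."""
    return 0.5 * (1.0 + np.tanh(np.multiply(G, P * np.asarray(x) - theta)))


def static_thresholds(w, variant: str):
    """Static thresholds: per-node half row sum (SL) or its mean (SG)."""
    weights = w.weights if hasattr(w, "weights") else np.asarray(w)
    local = 0.5 * weights.sum(axis=1)
    if variant == "SL":
        return local
    if variant == "SG":
        return float(local.mean())
    raise ValueError("static thresholds are defined for SL and SG only")


def initial_state(w, cfg: ModelConfig, a0: np.ndarray) -> NetworkState:
    """Build the start state from a binary output pattern.

    The binary pattern is assigned directly to the potentials; SL/SG
    thresholds start at their static values, the DG threshold at the
    pattern mean.
    """
    x = np.asarray(a0, dtype=float).copy()
    if cfg.variant == "DG":
        theta = np.asarray(float(x.mean()))
    else:
        theta = np.asarray(static_thresholds(w, cfg.variant))
    return NetworkState(x=x, theta=theta, t=0.0)


def random_initial_pattern(n: int, f0: float, seed) -> np.ndarray:
    """Binary vector with each node independently active with probability f0."""
    if not (0.0 < f0 < 1.0):
        raise ValueError("f0 must lie strictly in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return (rng.random(n) < f0).astype(float)


def detect_equilibrium(xbar_window: np.ndarray, eps: float = EQ_EPS,
                       floor: float = EQ_FLOOR) -> bool:
    """Relative stop rule on the node-averaged potential.

    ``xbar_window`` holds the recent values of the mean potential spanning
    the averaging window, last element = current value.  Returns True when
    ``|<xbar>_T - xbar(t)| / max(|xbar(t)|, floor) < eps``.
    """
    xbar_window = np.asarray(xbar_window, dtype=float)
    current = xbar_window[-1]
    avg = xbar_window.mean()
    return bool(abs(avg - current) / max(abs(current), floor) < eps)


def _step_batch(X, Theta, cfg: ModelConfig, W, rng, G=None, theta0=None):
    """One Euler(-Maruyama) step for a batch of states.

    X: (B, N); Theta: (B, N) for SL, (B,) for SG/DG.  ``G`` optionally
    overrides the scalar gain with a per-row vector (B,).  Returns the
    updated (X, Theta).
    """
    gain = cfg.G if G is None else np.asarray(G)[:, None]
    th = Theta if Theta.ndim == 2 else Theta[:, None]
    A = 0.5 * (1.0 + np.tanh(gain * (cfg.P * X - th)))
    drive = A @ W  # W symmetric: equals A @ W.T
    X = X + (cfg.dt / cfg.tau_x) * (drive - X)
    if cfg.sigma_x > 0:
        fac = cfg._noise_factor(cfg.tau_x)
        X = X + cfg.sigma_x * fac * np.sqrt(cfg.dt) * rng.standard_normal(X.shape)
    if cfg.variant == "DG":
        Theta = Theta + (cfg.dt / cfg.tau_theta) * (A.mean(axis=1) - Theta)
        if cfg.sigma_theta > 0:
            fac = cfg._noise_factor(cfg.tau_theta)
            Theta = Theta + cfg.sigma_theta * fac * np.sqrt(cfg.dt) * rng.standard_normal(Theta.shape)
    elif cfg.sigma_theta > 0:
        # static thresholds become Ornstein-Uhlenbeck around their rest value
        rest = theta0
        fac = cfg._noise_factor(cfg.tau_theta)
        Theta = Theta + (cfg.dt / cfg.tau_theta) * (rest - Theta) \
            + cfg.sigma_theta * fac * np.sqrt(cfg.dt) * rng.standard_normal(Theta.shape)
    return X, Theta, A


def step(state: NetworkState, cfg: ModelConfig, w, rng=None) -> NetworkState:
    """Advance one state by a single integration step of dt.

    With both noise strengths zero the update is exactly the deterministic
    Euler scheme.  Raises :class:`NonFiniteStateError` (naming the first
    offending node) if the update produces a non-finite potential.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    W = w.weights if hasattr(w, "weights") else np.asarray(w)
    X = state.x[None, :]
    theta = np.asarray(state.theta, dtype=float)
    if cfg.variant == "SL":
        Theta = theta[None, :]
    else:
        Theta = np.atleast_1d(theta).astype(float)
    theta0 = static_thresholds(W, cfg.variant) if cfg.variant != "DG" else None
    X, Theta, _ = _step_batch(X, Theta, cfg, W, rng, theta0=theta0)
    x_new = X[0]
    if not np.all(np.isfinite(x_new)):
        node = int(np.flatnonzero(~np.isfinite(x_new))[0])
        raise NonFiniteStateError(node, state.t + cfg.dt)
    theta_new = Theta[0] if cfg.variant == "SL" else np.asarray(float(Theta[0]))
    return NetworkState(x=x_new, theta=theta_new, t=state.t + cfg.dt)


def simulate(
    x0: np.ndarray,
    cfg: ModelConfig,
    w,
    duration: float,
    record_stride: int = 1,
    stop_at_equilibrium: bool = False,
    eq_window: float = EQ_WINDOW,
    eq_eps: float = EQ_EPS,
    rng=None,
) -> Trajectory:
    """Integrate a single initial output pattern and record the trajectory.

    ``x0`` is assigned to the potentials (binary sampling protocol); see
    :func:`initial_state` for the threshold initialization.  When
    ``stop_at_equilibrium`` the run ends as soon as the relative stop rule
    fires (tested once the window is spanned), else after ``duration`` ms.
    """
    if duration < cfg.dt:
        raise ValueError("duration must be at least one integration step")
    W = w.weights if hasattr(w, "weights") else np.asarray(w)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    state = initial_state(w, cfg, np.asarray(x0, dtype=float))
    n_steps = int(round(duration / cfg.dt))
    win_steps = max(1, int(round(eq_window / cfg.dt)))
    xbar_buf = np.empty(win_steps)
    times, xs, thetas = [state.t], [state.x.copy()], [np.array(state.theta, copy=True)]
    terminated = "t_max"
    theta0 = static_thresholds(W, cfg.variant) if cfg.variant != "DG" else None
    X = state.x[None, :]
    Theta = state.theta[None, :] if cfg.variant == "SL" else np.atleast_1d(state.theta).astype(float)
    t = 0.0
    for k in range(1, n_steps + 1):
        X, Theta, _ = _step_batch(X, Theta, cfg, W, rng, theta0=theta0)
        if not np.all(np.isfinite(X)):
            node = int(np.flatnonzero(~np.isfinite(X[0]))[0])
            raise NonFiniteStateError(node, t + cfg.dt)
        t = k * cfg.dt
        xbar_buf[(k - 1) % win_steps] = X[0].mean()
        if k % record_stride == 0:
            times.append(t)
            xs.append(X[0].copy())
            thetas.append(Theta[0].copy() if cfg.variant == "SL" else float(Theta[0]))
        if stop_at_equilibrium and k >= win_steps:
            order = np.roll(xbar_buf, -(k % win_steps))
            if detect_equilibrium(order, eps=eq_eps):
                terminated = "equilibrium"
                break
    return Trajectory(
        times=np.asarray(times),
        states=np.asarray(xs),
        thetas=np.asarray(thetas),
        record_stride=record_stride,
        config=cfg,
        terminated=terminated,
    )


def relax(
    w,
    cfg: ModelConfig,
    X0: np.ndarray,
    t_max: float = RELAX_CAP,
    eq_window: float = EQ_WINDOW,
    eq_eps: float = EQ_EPS,
    check_interval: int = 10,
    rng=None,
    gains: Optional[np.ndarray] = None,
    stop_at_equilibrium: bool = True,
):
    """Relax a batch of initial output patterns toward their attractors.

    Parameters
    ----------
    X0
        (B, N) batch of initial binary patterns (assigned to potentials).
    t_max
        Cap on simulated time (ms) when equilibrium is not reached.
    gains
        Optional per-row gain override (used by gain sweeps).

    Returns
    -------
    X_final : (B, N) final potentials
    Theta_final : (B, N) or (B,) final thresholds
    equilibrated : (B,) bool, True when the stop rule fired before t_max
    t_final : (B,) stop time of each run (ms)
    """
    W = w.weights if hasattr(w, "weights") else np.asarray(w)
    X0 = np.atleast_2d(np.asarray(X0, dtype=float))
    B, N = X0.shape
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    X = X0.copy()
    if cfg.variant == "SL":
        Theta = np.tile(static_thresholds(W, "SL"), (B, 1))
    elif cfg.variant == "SG":
        Theta = np.full(B, static_thresholds(W, "SG"))
    else:
        Theta = X0.mean(axis=1).copy()
    theta0 = static_thresholds(W, cfg.variant) if cfg.variant != "DG" else None

    n_steps = int(round(t_max / cfg.dt))
    win_steps = max(1, int(round(eq_window / cfg.dt)))
    active = np.arange(B)
    X_out = np.empty_like(X)
    Theta_out = np.empty_like(Theta)
    equilibrated = np.zeros(B, dtype=bool)
    t_final = np.full(B, t_max)
    buf = np.zeros((B, win_steps))  # ring buffer of mean potentials
    rolsum = np.zeros(B)
    G_rows = None if gains is None else np.asarray(gains, dtype=float)

    for k in range(1, n_steps + 1):
        g = None if G_rows is None else G_rows
        X, Theta, _ = _step_batch(X, Theta, cfg, W, rng, G=g, theta0=theta0)
        if not np.all(np.isfinite(X)):
            node = int(np.flatnonzero(~np.isfinite(X))[0] % X.shape[1])
            raise NonFiniteStateError(node, k * cfg.dt)
        xbar = X.mean(axis=1)
        slot = (k - 1) % win_steps
        rolsum += xbar - buf[:, slot]
        buf[:, slot] = xbar
        if stop_at_equilibrium and k >= win_steps and k % check_interval == 0:
            rel = np.abs(rolsum / win_steps - xbar) / np.maximum(np.abs(xbar), EQ_FLOOR)
            done = rel < eq_eps
            if np.any(done):
                idx = active[done]
                X_out[idx] = X[done]
                Theta_out[idx] = Theta[done]
                equilibrated[idx] = True
                t_final[idx] = k * cfg.dt
                keep = ~done
                X, Theta, buf, rolsum, active = (
                    X[keep], Theta[keep], buf[keep], rolsum[keep], active[keep])
                if G_rows is not None:
                    G_rows = G_rows[keep]
                if active.size == 0:
                    break
    if active.size:
        X_out[active] = X
        Theta_out[active] = Theta
    return X_out, Theta_out, equilibrated, t_final
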