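"""Hemodynamic (BOLD-like) signal reconstruction and functional
connectivity dynamics.

The pipeline is: block-average the simulated node outputs to 100 Hz,
convolve with a damped-sinusoid hemodynamic kernel, decimate to 0.5 Hz,
remove each node's temporal mean, then slide a window to obtain a sequence
of FC matrices whose vectorized upper triangles are correlated pairwise
into the FCD matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import fftconvolve

#: intermediate sampling rate for the convolution (Hz)
CONV_RATE = 100.0
#: final BOLD sampling rate (Hz)
BOLD_RATE = 0.5


@dataclass
class BoldSeries:
    """Detrended hemodynamic samples, one column per node."""

    values: np.ndarray  # (T, N)
    rate: float = BOLD_RATE
    labels: Optional[tuple] = None

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.n_samples / self.rate


@dataclass
class FCDMatrix:
    """Time-by-time correlation matrix of windowed FC vectors."""

    values: np.ndarray  # (T', T')
    window: float       # minutes
    step: int           # samples

    def off_diagonal(self) -> np.ndarray:
        iu = np.triu_indices(self.values.shape[0], k=1)
        return self.values[iu]


def balloon_kernel(
    dt: float,
    tau_s: float = 0.8,
    tau_f: float = 0.4,
    T_param: float = 10.0,
    support: float = 15.0,
    normalize: bool = True,
    omega_form: str = "taus_T",
) -> np.ndarray:
    """Damped-sinusoid hemodynamic impulse response sampled at ``dt`` seconds.

    H(t) = exp(-t / (2 tau_s)) sin(omega t) / omega with
    omega = sqrt(1/tau_f - 1/(4 tau_s T_param))  (default reading), or
    omega = sqrt(1/tau_f - 1/(4 tau_s^2)) when ``omega_form="taus_sq"``.
    The kernel spans [0, support] (envelope < 1e-4 at the 15 s default) and
    is normalized to unit area unless disabled.
    """
    if omega_form == "taus_T":
        om2 = 1.0 / tau_f - 1.0 / (4.0 * tau_s * T_param)
    elif omega_form == "taus_sq":
        om2 = 1.0 / tau_f - 1.0 / (4.0 * tau_s**2)
    else:
        raise ValueError("omega_form must be 'taus_T' or 'taus_sq'")
    if om2 <= 0:
        raise ValueError(f"omega^2 = {om2:g} <= 0; kernel undefined")
    omega = np.sqrt(om2)
    t = np.arange(0.0, support + dt / 2, dt)
    h = np.exp(-0.5 * t / tau_s) * np.sin(omega * t) / omega
    if normalize:
        area = h.sum() * dt
        if area != 0:
            h = h / area
    return h


def simulate_bold(
    traj,
    tau_s: float = 0.8,
    tau_f: float = 0.4,
    T_param: float = 10.0,
    support: float = 15.0,
    signal: str = "output",
    labels=None,
) -> BoldSeries:
    """Convert a recorded trajectory into a detrended 0.5 Hz BOLD series.

    Per node: block-average the signal to 100 Hz, convolve causally with
    the hemodynamic kernel, keep every 200th sample of the 100 Hz stream
    (0.5 Hz), and subtract the temporal mean.  ``signal`` selects node
    outputs (default) or raw potentials.
    """
    if signal == "output":
        data = traj.outputs()
    elif signal == "potential":
        data = traj.states
    else:
        raise ValueError("signal must be 'output' or 'potential'")
    data = data[1:]  # row 0 is the initial condition; drop it so the
    # remaining samples tile full 10 ms blocks
    sample_dt_ms = traj.config.dt * traj.record_stride
    block = int(round((1000.0 / CONV_RATE) / sample_dt_ms))
    if block < 1:
        raise ValueError(
            f"trajectory sampled coarser ({sample_dt_ms} ms) than the "
            "100 Hz convolution grid"
        )
    T = (data.shape[0] // block) * block
    if T == 0:
        raise ValueError("trajectory too short for the 100 Hz block average")
    hi = data[:T].reshape(-1, block, data.shape[1]).mean(axis=1)  # 100 Hz
    kernel = balloon_kernel(1.0 / CONV_RATE, tau_s, tau_f, T_param, support)
    # edge-pad with the first sample: the signal is assumed to have sat at
    # its initial value before recording, so a constant input stays constant
    pad = np.repeat(hi[:1], len(kernel) - 1, axis=0)
    conv = fftconvolve(np.vstack([pad, hi]), kernel[:, None], axes=0)
    conv = conv[len(kernel) - 1: len(kernel) - 1 + hi.shape[0]] / CONV_RATE
    stride = int(round(CONV_RATE / BOLD_RATE))
    low = conv[::stride]
    if low.shape[0] < 2:
        raise ValueError("trajectory too short: fewer than two 0.5 Hz samples")
    low = low - low.mean(axis=0, keepdims=True)
    return BoldSeries(values=low, rate=BOLD_RATE, labels=labels)


def sliding_fc(bold: BoldSeries, window: float = 1.0, step: int = 1) -> np.ndarray:
    """Sequence of windowed N x N Pearson FC matrices.

    ``window`` is in minutes (30 samples at 0.5 Hz for the 1 min default),
    ``step`` in samples.  Zero-variance nodes give 0 rows/columns with a
    warning.  Returns an array of shape (T', N, N) with
    T' = (n_samples - window_samples) // step + 1 positions.
    """
    w_samples = int(round(window * 60.0 * bold.rate))
    T, N = bold.values.shape
    if w_samples > T:
        raise ValueError(
            f"window of {w_samples} samples longer than series ({T} samples)"
        )
    n_pos = (T - w_samples) // step + 1
    out = np.empty((n_pos, N, N))
    warned = False
    for p in range(n_pos):
        seg = bold.values[p * step: p * step + w_samples]
        sd = seg.std(axis=0)
        zero = sd < 1e-12
        if np.any(zero) and not warned:
            warnings.warn("zero-variance node(s) in FC window; entries set to 0")
            warned = True
        with np.errstate(invalid="ignore", divide="ignore"):
            fc = np.corrcoef(seg, rowvar=False)
        fc = np.where(np.isfinite(fc), fc, 0.0)
        fc[zero, :] = 0.0
        fc[:, zero] = 0.0
        np.fill_diagonal(fc, 1.0)
        out[p] = fc
    return out


def fcd_matrix(fc_sequence: np.ndarray, node_subset=None,
               window: float = 1.0, step: int = 1) -> FCDMatrix:
    """Correlate the vectorized upper-triangle FC of every window pair.

    ``node_subset`` optionally restricts to a boolean node mask before the
    upper triangle is taken.  The result is symmetric with unit diagonal.
    """
    fc = np.asarray(fc_sequence)
    if fc.shape[0] < 2:
        raise ValueError("need at least two window positions")
    if node_subset is not None:
        mask = np.asarray(node_subset, dtype=bool)
        fc = fc[:, mask][:, :, mask]
    n = fc.shape[1]
    iu = np.triu_indices(n, k=1)
    vecs = fc[:, iu[0], iu[1]]
    sd = vecs.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.corrcoef(vecs)
    mat = np.where(np.isfinite(mat), mat, 0.0)
    mat[sd < 1e-12, :] = 0.0
    mat[:, sd < 1e-12] = 0.0
    # constant FC vectors across windows (e.g. stationary input) are
    # perfectly self-similar: restore the degenerate correlations to 1
    both_const = np.outer(sd < 1e-12, sd < 1e-12)
    if np.any(both_const):
        const_vec = vecs[sd < 1e-12]
        same = np.allclose(const_vec, const_vec[:1], atol=1e-12)
        if same:
            mat[both_const] = 1.0
    np.fill_diagonal(mat, 1.0)
    mat = 0.5 * (mat + mat.T)
    return FCDMatrix(values=mat, window=window, step=step)


def attractor_fc(aset, weighted: bool = True) -> np.ndarray:
    """Pearson correlation of node activities across an attractor set.

    Attractors are the observations and nodes the variables; each
    attractor contributes proportionally to its cardinality (switchable to
    unweighted).  Nodes constant across the set give 0 rows/columns with a
    warning (diagonal stays 1).
    """
    if len(aset) < 2:
        raise ValueError("need at least two attractors")
    P = aset.patterns()  # (m, N)
    wts = aset.cardinalities().astype(float) if weighted else np.ones(len(aset))
    wts = wts / wts.sum()
    mean = wts @ P
    dev = P - mean[None, :]
    cov = (dev * wts[:, None]).T @ dev
    var = np.diag(cov).copy()
    zero = var < 1e-24
    if np.any(zero):
        warnings.warn("node(s) constant across attractors; FC rows set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.sqrt(np.outer(var, var))
    corr = np.where(np.isfinite(corr), corr, 0.0)
    corr[zero, :] = 0.0
    corr[:, zero] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr


def compare_fc(a: np.ndarray, b: np.ndarray, mask: str = "all",
               hemisphere=None) -> float:
    """Pearson correlation of two FC matrices over masked upper-triangle entries.

    ``mask`` selects all off-diagonal pairs, only intra-hemispheric pairs,
    or only inter-hemispheric pairs (the last two need hemisphere tags).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    keep = np.ones(iu[0].size, dtype=bool)
    if mask != "all":
        if hemisphere is None:
            raise ValueError("hemispheric masks require hemisphere tags")
        hemi = np.asarray(hemisphere)
        same = hemi[iu[0]] == hemi[iu[1]]
        keep = same if mask == "intra_hemispheric" else ~same
        if mask not in ("intra_hemispheric", "inter_hemispheric"):
            raise ValueError(f"unknown mask {mask!r}")
    if not np.any(keep):
        raise ValueError("mask selects no entries")
    va, vb = a[iu][keep], b[iu][keep]
    return float(np.corrcoef(va, vb)[0, 1])
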