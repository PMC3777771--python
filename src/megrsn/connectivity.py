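"""Phase lag index (PLI) connectivity.

The PLI between two signals is the absolute mean of the sign of the sine of
their instantaneous phase difference,

    PLI = | < sign( sin(phi_a(t_k) - phi_b(t_k)) ) > |,   k = 1..N_s,

with the phase difference taken in [-pi, pi].  It measures the *asymmetry* of
the phase-difference distribution around zero: a consistent nonzero phase lag
drives PLI toward 1, while zero-lag (volume-conducted) coupling and symmetric
phase scatter leave it at 0.  Instantaneous phase comes from the analytic
signal (Hilbert transform).

By convention sign(0) = 0, so a signal paired with an identical copy of
itself scores exactly 0, and the matrix diagonal is fixed at 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .bands import FrequencyBand
from .preprocess import EpochSet

__all__ = [
    "PhaseSeries",
    "ConnectivityMatrix",
    "instantaneous_phase",
    "pli_pair",
    "pli_matrix",
    "mean_pli",
]


@dataclass
class PhaseSeries:
    """Per-sample instantaneous phase in radians, wrapped to [-pi, pi]."""

    values: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.abs(self.values) > np.pi + 1e-12):
            raise ValueError("phase values must lie in [-pi, pi]")


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI PLI matrix; diagonal 0, off-diagonal in [0, 1]."""

    roi_labels: tuple[str, ...]
    values: np.ndarray
    band: FrequencyBand | None = None
    n_epochs_averaged: int = 1

    def __post_init__(self) -> None:
        self.roi_labels = tuple(self.roi_labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.roi_labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be 0 by convention")
        off = self.values[~np.eye(n, dtype=bool)]
        if off.size and (off.min() < -1e-12 or off.max() > 1 + 1e-12):
            raise ValueError("off-diagonal PLI values must lie in [0, 1]")

    @property
    def n_pairs(self) -> int:
        """Number of distinct unordered ROI pairs (78 ROIs -> 3003)."""
        n = len(self.roi_labels)
        return n * (n - 1) // 2


def instantaneous_phase(series: np.ndarray, rate: float = 1.0) -> PhaseSeries:
    """Phase of the analytic signal, per sample.

    A pure sinusoid yields a phase advancing linearly at its angular
    frequency (modulo 2*pi).  An all-zero series has no defined phase.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a single 1-D series")
    if x.size < 64:
        raise ValueError(f"series too short for phase estimation ({x.size} < 64)")
    if not np.any(x):
        raise ValueError("phase of an all-zero series is undefined")
    return PhaseSeries(values=np.angle(hilbert(x)), rate=rate)


def _phase_values(p) -> np.ndarray:
    return p.values if isinstance(p, PhaseSeries) else np.asarray(p, dtype=float)


def _trim_slice(n: int, edge_trim: float) -> slice:
    if not 0.0 <= edge_trim <= 0.25:
        raise ValueError(f"edge_trim must lie in [0, 0.25], got {edge_trim}")
    k = int(round(edge_trim * n))
    return slice(k, n - k if k else n)


def pli_pair(phase_a, phase_b, edge_trim: float = 0.05) -> float:
    """PLI of one phase-series pair.

    ``edge_trim`` drops that fraction of samples at each end before the
    sign-sine mean (default 5% per side), discarding Hilbert edge effects.
    Symmetric in its arguments and invariant to adding any constant to both
    phase series.
    """
    a, b = _phase_values(phase_a), _phase_values(phase_b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    sl = _trim_slice(a.size, edge_trim)
    return float(np.abs(np.mean(np.sign(np.sin(a[sl] - b[sl])))))


def pli_matrix(
    epochs: EpochSet,
    edge_trim: float = 0.05,
    epoch_mode: str = "average",
) -> ConnectivityMatrix:
    """PLI for all unordered channel pairs of an epoch set.

    ``epoch_mode="average"`` (default) computes a PLI matrix per epoch and
    averages the matrices arithmetically — epochs are separate stationary
    segments, and averaging avoids spurious phase discontinuities at epoch
    boundaries.  ``"concatenate"`` instead pools the signed sin-difference
    samples of all epochs before taking the absolute mean.
    """
    if epochs.n_epochs == 0:
        raise ValueError("PLI undefined for an empty epoch set")
    n_ch = len(epochs.roi_labels)
    if n_ch < 2:
        raise ValueError("need at least 2 channels")
    if epoch_mode not in ("average", "concatenate"):
        raise ValueError(f"unknown epoch_mode {epoch_mode!r}")

    acc = np.zeros((n_ch, n_ch))
    for ep in epochs.epochs:
        phases = np.angle(hilbert(ep, axis=-1))
        sl = _trim_slice(ep.shape[1], edge_trim)
        phases = phases[:, sl]
        signed = np.zeros((n_ch, n_ch))
        for i in range(n_ch - 1):
            d = phases[i + 1 :] - phases[i][None, :]
            m = np.mean(np.sign(np.sin(d)), axis=-1)
            signed[i, i + 1 :] = m
            signed[i + 1 :, i] = -m
        acc += np.abs(signed) if epoch_mode == "average" else signed
    values = np.abs(acc) / epochs.n_epochs if epoch_mode == "concatenate" else acc / epochs.n_epochs
    np.fill_diagonal(values, 0.0)
    return ConnectivityMatrix(
        roi_labels=epochs.roi_labels,
        values=values,
        band=epochs.band,
        n_epochs_averaged=epochs.n_epochs,
    )


def mean_pli(matrix: ConnectivityMatrix, roi_subset=None) -> float:
    """Mean PLI over within-subset unordered pairs (all pairs if no subset).

    Connections from the subset to the rest of the matrix are excluded: only
    pairs with *both* ends inside the subset count.
    """
    labels = matrix.roi_labels
    if roi_subset is None:
        idx = np.arange(len(labels))
    else:
        subset = list(roi_subset)
        unknown = [s for s in subset if s not in labels]
        if unknown:
            raise KeyError(f"labels not in matrix: {unknown}")
        if len(set(subset)) < 2:
            raise ValueError("subset must contain at least 2 distinct labels")
        pos = {lab: i for i, lab in enumerate(labels)}
        idx = np.array([pos[s] for s in subset])
    sub = matrix.values[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(sub[iu].mean())
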