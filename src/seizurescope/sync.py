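"""Phase synchronization and the eigenvalue-based global synchronization index.

Each channel's instantaneous phase is the angle of the analytic signal
(Hilbert transform) of the mean-removed dF/F trace.  The pairwise matrix
holds phase-locking values, S[i,j] = |<exp(i(phi_i - phi_j))>_t|, which is 1
for a constant relative phase and ~1/sqrt(T) for independent phases.  The
global index maps the largest eigenvalue of S onto [0, 1]:

    GSI = clip((lambda_max - 1) / (N - 1), 0, 1)

so a fully synchronized network (all entries 1, lambda_max = N) scores 1 and
fully uncorrelated series (off-diagonal 0, lambda_max = 1 — or the all-zero
idealization, lambda_max = 0) score 0.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .core import TraceMatrix
from .exceptions import InputError, NumericalError


@dataclass
class SyncResult:
    """Pairwise phase-synchronization matrix plus its global index."""

    matrix: np.ndarray
    global_index: float
    labels: list[str]


def instantaneous_phase(x: np.ndarray) -> np.ndarray:
    """Instantaneous phase (radians, in (-pi, pi]) of a 1-D trace."""
    x = np.asarray(x, dtype=float)
    if len(x) < 16:
        raise InputError("trace too short for a meaningful analytic signal")
    x0 = x - x.mean()
    if np.allclose(x0, 0.0):
        raise NumericalError("constant trace has no defined phase")
    return np.angle(hilbert(x0))


def phase_sync_matrix(phases: np.ndarray) -> np.ndarray:
    """Pairwise phase-locking-value matrix from a (time, channels) phase array."""
    phases = np.asarray(phases, dtype=float)
    if phases.ndim != 2 or phases.shape[1] < 2:
        raise InputError("need a (time, >=2 channels) phase array")
    z = np.exp(1j * phases)
    t = phases.shape[0]
    s = np.abs(z.conj().T @ z) / t
    s = 0.5 * (s + s.T)
    np.fill_diagonal(s, 1.0)
    return np.clip(s, 0.0, 1.0)


def global_sync_index(s: np.ndarray) -> float:
    """Eigenvalue-based global synchronization index of a pairwise matrix."""
    s = np.asarray(s, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise InputError("synchronization matrix must be square")
    if not np.allclose(s, s.T, atol=1e-10):
        raise InputError("synchronization matrix must be symmetric")
    n = s.shape[0]
    if n < 2:
        raise InputError("need at least two channels")
    lam_max = float(np.linalg.eigvalsh(s)[-1])
    return float(np.clip((lam_max - 1.0) / (n - 1.0), 0.0, 1.0))


def correlation_matrix(dff: TraceMatrix) -> np.ndarray:
    """Pearson correlation matrix of the channels of a trace matrix.

    Zero-variance channels get zero correlation with everything (with a
    warning) but keep a unit diagonal.
    """
    x = dff.values
    if x.shape[0] < 2:
        raise InputError("need at least 2 samples per channel")
    sd = x.std(axis=0)
    dead = sd == 0
    out = np.zeros((x.shape[1], x.shape[1]))
    live = ~dead
    if dead.any():
        warnings.warn(
            f"zero-variance channels set to zero correlation: "
            f"{[dff.labels[i] for i in np.flatnonzero(dead)]}",
            stacklevel=2,
        )
    if live.sum() >= 2:
        out[np.ix_(live, live)] = np.corrcoef(x[:, live].T)
    elif live.sum() == 1:
        out[np.ix_(live, live)] = 1.0
    np.fill_diagonal(out, 1.0)
    return out


def compute_synchronization(dff: TraceMatrix) -> SyncResult:
    """Phases -> PLV matrix -> global index for a whole dF/F matrix."""
    if dff.kind != "dff":
        raise InputError("compute_synchronization expects a dff-kind TraceMatrix")
    phases = np.column_stack(
        [instantaneous_phase(dff.values[:, j]) for j in range(dff.n_channels)]
    )
    s = phase_sync_matrix(phases)
    return SyncResult(matrix=s, global_index=global_sync_index(s),
                      labels=list(dff.labels))
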