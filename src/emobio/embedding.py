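"""Time-delay phase-space reconstruction."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["Embedding", "autocorr_lag", "embed"]


@dataclass(frozen=True)
class Embedding:
    """Delay-vector matrix: ``points[i, j] = x[i + j * tau]``.

    ``M = N - (m - 1) * tau`` rows of dimension ``m``.
    """

    points: np.ndarray
    m: int
    tau: int
    N: int

    def __post_init__(self) -> None:
        M = self.N - (self.m - 1) * self.tau
        if self.points.shape != (M, self.m):
            raise ValueError(f"points must be ({M}, {self.m}), got {self.points.shape}")

    @property
    def M(self) -> int:
        return self.points.shape[0]


def autocorr(x: np.ndarray) -> np.ndarray:
    """Biased sample autocorrelation, acf[0] = 1 (FFT-based)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    xc = x - x.mean()
    var = np.dot(xc, xc)
    if var == 0:
        return np.concatenate([[1.0], np.zeros(n - 1)])
    nfft = int(2 ** np.ceil(np.log2(2 * n - 1)))
    spec = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(spec * np.conj(spec), nfft)[:n]
    return acov / var


def autocorr_lag(x) -> int:
    """Embedding delay: lag of the autocorrelation's first local minimum.

    Falls back to the first zero crossing, then ``max(len(x) // 10, 1)``,
    when no interior local minimum exists (with a warning for degenerate
    constant input).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0:
        warnings.warn("constant signal: autocorrelation undefined, using fallback lag",
                      stacklevel=2)
        return max(len(x) // 10, 1)
    acf = autocorr(x)
    interior = np.flatnonzero((acf[1:-1] < acf[:-2]) & (acf[1:-1] < acf[2:]))
    if len(interior):
        return int(interior[0] + 1)
    below = np.flatnonzero(acf < 0)
    if len(below):
        return int(below[0])
    return max(len(x) // 10, 1)


def embed(x, m: int, tau: int) -> Embedding:
    """Delay-embed a scalar series into ``m`` dimensions with lag ``tau``."""
    x = np.asarray(x, dtype=float)
    if m < 1 or tau < 1:
        raise ValueError("m and tau must be >= 1")
    N = len(x)
    M = N - (m - 1) * tau
    if M < 1:
        raise ValueError(
            f"series of length {N} too short for m={m}, tau={tau}; "
            f"need at least {(m - 1) * tau + 1} samples"
        )
    idx = np.arange(M)[:, None] + tau * np.arange(m)[None, :]
    return Embedding(points=x[idx], m=m, tau=tau, N=N)
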