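"""Non-linear signal descriptors on delay embeddings and scalar series.

Implements the spatial filling index (grid-occupancy concentration of a
2-D phase portrait), the largest Lyapunov exponent (Rosenstein
nearest-neighbour divergence), the correlation dimension
(Grassberger-Procaccia), and approximate / sample entropy (Pincus;
Richman-Moorman).  All are deterministic; point subsampling for the
correlation sum uses an even stride, not randomness.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .embedding import Embedding, embed

__all__ = [
    "feat_sfi",
    "feat_lyapunov",
    "feat_corrdim",
    "correlation_sum",
    "entropy_pair",
    "feat_apen",
    "feat_sampen",
]


# ---------------------------------------------------------------------------
# spatial filling index
# ---------------------------------------------------------------------------

def feat_sfi(emb: Embedding, grid: int = 10) -> float:
    """Occupancy concentration of the 2-D trajectory on a grid x grid mesh.

    The trajectory is min-max normalized to the unit square; with ``p_ij``
    the fraction of points in cell (i, j), the index is
    ``sum(p_ij^2) / grid^2``: ``1/grid^2`` when all points share a cell,
    ``1/grid^4`` under exactly uniform occupancy.
    """
    if emb.m != 2:
        raise ValueError("spatial filling index is defined on 2-D embeddings")
    if grid < 1:
        raise ValueError("grid must be >= 1")
    pts = emb.points
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    span = hi - lo
    if np.any(span == 0):
        warnings.warn("degenerate embedding axis (zero range); SFI computed on the "
                      "collapsed distribution", stacklevel=2)
    unit = np.where(span > 0, (pts - lo) / np.where(span > 0, span, 1.0), 0.0)
    cells = np.minimum((unit * grid).astype(int), grid - 1)
    flat = cells[:, 0] * grid + cells[:, 1]
    counts = np.bincount(flat, minlength=grid * grid)
    p = counts / emb.M
    return float(np.sum(p**2) / grid**2)


# ---------------------------------------------------------------------------
# largest Lyapunov exponent (Rosenstein)
# ---------------------------------------------------------------------------

def feat_lyapunov(
    emb: Embedding,
    rate_hz: float | None = None,
    min_tsep: int | None = None,
    n_steps: int = 10,
    fit_range: tuple[int, int] = (1, 8),
) -> float:
    """Largest Lyapunov exponent via nearest-neighbour divergence.

    For every state, the nearest neighbour with temporal separation larger
    than ``min_tsep`` (default: the embedding lag) is tracked forward; the
    exponent is the least-squares slope of the mean log divergence over
    ``fit_range`` (in steps).  Step 0 is excluded by default: the nearest
    neighbour is atypically close by construction and its relaxation back
    to typical spacing mimics divergence on non-chaotic data.  Returned in
    nats/sample, or nats/second when ``rate_hz`` is given.
    """
    M = emb.M
    if M < 50:
        raise ValueError(f"need at least 50 embedded points, got {M}")
    if min_tsep is None:
        min_tsep = max(emb.tau, 1)
    d = squareform(pdist(emb.points))
    for k in range(min(min_tsep, M - 1) + 1):  # mask |i - j| <= min_tsep
        np.fill_diagonal(d[k:, :], np.inf)
        np.fill_diagonal(d[:, k:], np.inf)
    nn = np.argmin(d, axis=1)
    if not np.isfinite(d[np.arange(M), nn]).any():
        raise ValueError("no valid nearest neighbours (min_tsep too large)")

    logs = np.full((n_steps + 1, M), np.nan)
    for k in range(n_steps + 1):
        valid = np.flatnonzero((np.arange(M) + k < M) & (nn + k < M))
        if len(valid) == 0:
            break
        dk = np.linalg.norm(emb.points[valid + k] - emb.points[nn[valid] + k], axis=1)
        ok = valid[dk > 0]
        logs[k, ok] = np.log(dk[dk > 0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        y = np.nanmean(logs, axis=1)
    k0, k1 = fit_range
    ks = np.arange(k0, min(k1, n_steps) + 1)
    ks = ks[np.isfinite(y[ks])]
    if len(ks) < 2:
        raise ValueError("not enough divergence steps to fit a slope")
    slope = np.polyfit(ks, y[ks], 1)[0]
    return float(slope * rate_hz) if rate_hz else float(slope)


# ---------------------------------------------------------------------------
# correlation dimension (Grassberger-Procaccia)
# ---------------------------------------------------------------------------

def correlation_sum(points: np.ndarray, r) -> np.ndarray:
    """C(r) = 2/(M(M-1)) * #{i<j : ||Xi - Xj|| < r} for each radius."""
    M = len(points)
    if M < 2:
        raise ValueError("need at least 2 points")
    d = pdist(points)
    r = np.atleast_1d(np.asarray(r, dtype=float))
    return np.count_nonzero(d[None, :] < r[:, None], axis=1) / (0.5 * M * (M - 1))


def feat_corrdim(
    emb: Embedding,
    n_radii: int = 12,
    radius_percentiles: tuple[float, float] = (5.0, 50.0),
    max_points: int = 400,
) -> float:
    """Correlation dimension: slope of log C(r) vs log r.

    Radii are log-spaced between the 5th and 50th percentile of non-zero
    pairwise distances (the configured scaling region).  Embeddings with
    more than ``max_points`` states are evenly strided down for the O(M^2)
    pair count.
    """
    pts = emb.points
    if len(pts) > max_points:
        stride = int(np.ceil(len(pts) / max_points))
        pts = pts[::stride]
    d = pdist(pts)
    d = d[d > 0]
    if len(d) == 0:
        raise ValueError("all pairwise distances are zero")
    lo, hi = np.percentile(d, radius_percentiles)
    if lo <= 0 or hi <= lo:
        lo, hi = d.min(), d.max()
    radii = np.geomspace(lo, hi, n_radii)
    C = correlation_sum(pts, radii)
    keep = C > 0
    if keep.sum() < 2:
        raise ValueError("correlation sum vanishes over the radius grid")
    slope = np.polyfit(np.log(radii[keep]), np.log(C[keep]), 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# approximate & sample entropy
# ---------------------------------------------------------------------------

def _chebyshev_template_dists(x: np.ndarray, m: int, d1: np.ndarray | None = None) -> np.ndarray:
    """All-pairs Chebyshev distances between the x[i:i+m] templates."""
    if d1 is None:
        d1 = np.abs(x[:, None] - x[None, :])
    n = len(x) - m + 1
    d = d1[:n, :n].copy()
    for k in range(1, m):
        np.maximum(d, d1[k : k + n, k : k + n], out=d)
    return d


def entropy_pair(x, m: int = 2, r: float = 0.2) -> tuple[float, float]:
    """(ApEn, SampEn) sharing one scalar-distance matrix; see the
    individual functions for the definitions."""
    x = np.asarray(x, dtype=float)
    if len(x) < 10 * m:
        raise ValueError(f"need at least {10 * m} samples for m={m}")
    tol = _resolve_r(x, r)
    d1 = np.abs(x[:, None] - x[None, :])
    dm = _chebyshev_template_dists(x, m, d1)
    dm1 = _chebyshev_template_dists(x, m + 1, d1)

    cm = np.count_nonzero(dm <= tol, axis=1)
    cm1 = np.count_nonzero(dm1 <= tol, axis=1)
    apen = float(np.mean(np.log(cm / dm.shape[0])) - np.mean(np.log(cm1 / dm1.shape[0])))

    n = len(x) - m
    iu = np.triu_indices(n, k=1)
    B = int(np.count_nonzero(dm[:n, :n][iu] <= tol))
    A = int(np.count_nonzero(dm1[iu] <= tol))
    sampen = float(-np.log(A / B)) if A > 0 and B > 0 else float("nan")
    return apen, sampen


def _resolve_r(x: np.ndarray, r: float) -> float:
    sd = x.std()
    if sd == 0:
        raise ValueError("constant signal: tolerance r = r_factor * SD is zero")
    return r * sd


def feat_apen(x, m: int = 2, r: float = 0.2) -> float:
    """Approximate entropy (self-matches included, Chebyshev distance).

    ``r`` is a multiple of the series' standard deviation.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 10 * m:
        raise ValueError(f"need at least {10 * m} samples for m={m}")
    tol = _resolve_r(x, r)

    def phi(mm: int) -> float:
        d = _chebyshev_template_dists(x, mm)
        counts = np.count_nonzero(d <= tol, axis=1)  # includes self-match
        return float(np.mean(np.log(counts / d.shape[0])))

    return phi(m) - phi(m + 1)


def feat_sampen(x, m: int = 2, r: float = 0.2) -> float:
    """Sample entropy (self-matches excluded); NaN when no template matches.

    Both template lengths use the first ``N - m`` templates, per the
    standard definition.  ``r`` is a multiple of the standard deviation.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 10 * m:
        raise ValueError(f"need at least {10 * m} samples for m={m}")
    tol = _resolve_r(x, r)
    n = len(x) - m  # templates considered at both lengths

    dm = _chebyshev_template_dists(x, m)[:n, :n]
    dm1 = _chebyshev_template_dists(x, m + 1)  # (n, n) already
    iu = np.triu_indices(n, k=1)
    B = int(np.count_nonzero(dm[iu] <= tol))
    A = int(np.count_nonzero(dm1[iu] <= tol))
    if A == 0 or B == 0:
        return float("nan")
    return float(-np.log(A / B))


def nonlinear_profile(
    x,
    rate_hz: float,
    lag: int,
    sfi_grid: int = 10,
    entropy_m: int = 2,
    entropy_r: float = 0.2,
) -> dict[str, float]:
    """All five non-linear features of one scalar series; NaN on failure."""
    out: dict[str, float] = {}

    def entropies() -> float:
        out["apen"], out["sampen"] = entropy_pair(x, m=entropy_m, r=entropy_r)
        return out["apen"]

    for name, fn in (
        ("sfi", lambda: feat_sfi(embed(x, 2, lag), grid=sfi_grid)),
        ("lyap", lambda: feat_lyapunov(embed(x, 3, lag))),
        ("corrdim", lambda: feat_corrdim(embed(x, 3, lag))),
        ("apen", entropies),
    ):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out[name] = fn()
        except ValueError:
            out[name] = float("nan")
            if name == "apen":
                out["sampen"] = float("nan")
    return out
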