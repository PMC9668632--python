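"""Static and sliding-window functional connectivity.

FC is expressed as Fisher-Z transformed Pearson correlations, vectorized
over the lower triangle of the symmetric component x component matrix in
column-major order (column 0 rows 1..n-1, then column 1 rows 2..n-1, ...).
With 47 components this gives 47*46/2 = 1081 pair values.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .prep import ComponentTimecourseSet

#: correlations are clipped to +/- (1 - 1e-7) before arctanh so the
#: Fisher-Z value stays finite while preserving ordering
R_MAX = 1.0 - 1e-7


def fisher_z(r):
    """Fisher-Z transform arctanh(r), with |r| clipped to 1 - 1e-7.

    Accepts scalars or arrays.  Values outside [-1, 1] beyond a 1e-12
    numerical slack raise.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1 + 1e-12):
        raise ValueError("correlation magnitude exceeds 1")
    z = np.arctanh(np.clip(arr, -R_MAX, R_MAX))
    return z if arr.shape else float(z)


def pair_index(n: int) -> list[tuple[int, int]]:
    """Ordered (i, j) pairs, i > j, column-major lower-triangle order."""
    return [(i, j) for j in range(n - 1) for i in range(j + 1, n)]


def _tri_rows_cols(n: int) -> tuple[np.ndarray, np.ndarray]:
    cols, rows = np.triu_indices(n, k=1)  # upper row-major == lower col-major
    return rows, cols


def vectorize_lower_triangle(M: np.ndarray) -> np.ndarray:
    """Vectorize a symmetric matrix's strict lower triangle (column-major)."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("matrix is not symmetric within 1e-10")
    rows, cols = _tri_rows_cols(M.shape[0])
    return M[rows, cols].copy()


def devectorize(v: np.ndarray, diag: float = 0.0) -> np.ndarray:
    """Inverse of :func:`vectorize_lower_triangle`; diagonal set to ``diag``."""
    v = np.asarray(v, dtype=float)
    m = v.shape[0]
    n = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if n * (n - 1) // 2 != m:
        raise ValueError(f"vector length {m} is not a triangular number")
    M = np.full((n, n), diag, dtype=float)
    rows, cols = _tri_rows_cols(n)
    M[rows, cols] = v
    M[cols, rows] = v
    np.fill_diagonal(M, diag)
    return M


@dataclass(frozen=True)
class FCVector:
    """Fisher-Z FC values for one participant, lower-triangle pair order."""

    values: np.ndarray
    pair_ids: tuple  # ((comp_i, comp_j), ...) with i > j in component order
    participant_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.shape[0] != len(self.pair_ids):
            raise ValueError("values must be 1-D and match pair_ids")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite FC values")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "pair_ids", tuple(self.pair_ids))

    @property
    def n_pairs(self) -> int:
        return self.values.shape[0]

    def as_matrix(self, diag: float = 0.0) -> np.ndarray:
        return devectorize(self.values, diag=diag)


@dataclass(frozen=True)
class WindowedFCSeries:
    """Sequence of Fisher-Z FC vectors, one per sliding window."""

    values: np.ndarray  # windows x n_pairs
    window_starts: np.ndarray  # 0-based inclusive start TR per window
    window_length: int
    slide: int
    pair_ids: tuple
    participant_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != len(self.pair_ids):
            raise ValueError("values must be windows x n_pairs")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "window_starts", np.asarray(self.window_starts))
        object.__setattr__(self, "pair_ids", tuple(self.pair_ids))

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.values.shape[1]


def _component_pair_ids(component_ids) -> tuple:
    n = len(component_ids)
    return tuple(
        (component_ids[i], component_ids[j]) for i, j in pair_index(n)
    )


def _corr_vector(block: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Pearson correlations (optionally weighted) of rows, vectorized lower tri."""
    if weights is None:
        C = np.corrcoef(block)
    else:
        w = weights / weights.sum()
        mu = block @ w
        X = block - mu[:, None]
        cov = (X * w) @ X.T
        sd = np.sqrt(np.diag(cov))
        C = cov / np.outer(sd, sd)
    rows, cols = _tri_rows_cols(block.shape[0])
    return C[rows, cols]


def static_fc(ts: ComponentTimecourseSet) -> FCVector:
    """Static FC: pairwise Pearson r over all timepoints, Fisher-Z transformed."""
    if ts.n_timepoints < 3:
        raise ValueError("static FC needs at least 3 timepoints")
    sd = ts.values.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [ts.component_ids[i] for i in dead]
        raise ValueError(f"zero-variance component(s): {names}")
    r = _corr_vector(ts.values)
    return FCVector(
        values=fisher_z(r),
        pair_ids=_component_pair_ids(ts.component_ids),
        participant_id=ts.participant_id,
    )


def _taper_weights(w: int, sigma: float = 3.0) -> np.ndarray:
    """Rectangle of length w convolved with a Gaussian kernel (sigma in TR)."""
    half = int(np.ceil(3 * sigma))
    x = np.arange(-half, half + 1, dtype=float)
    g = np.exp(-0.5 * (x / sigma) ** 2)
    g /= g.sum()
    rect = np.ones(w)
    return np.convolve(rect, g, mode="same")


def sliding_window_fc(
    ts: ComponentTimecourseSet,
    w: int = 22,
    s: int = 1,
    taper: str | None = None,
    taper_sigma: float = 3.0,
) -> WindowedFCSeries:
    """Sliding-window FC with window ``w`` TR and slide ``s`` TR.

    Window m covers TRs [m*s, m*s + w) (0-based, half-open); the number of
    windows is floor((T - w)/s) + 1.  ``taper`` may be ``None`` (rectangular)
    or ``"gaussian"`` (rectangle convolved with a Gaussian, sigma in TR).
    """
    T = ts.n_timepoints
    if w < 3:
        raise ValueError("window must span at least 3 TR")
    if w > T:
        raise ValueError(f"window w={w} exceeds scan length T={T}")
    if s < 1:
        raise ValueError("slide must be >= 1")
    if taper not in (None, "none", "gaussian"):
        raise ValueError(f"unknown taper {taper!r}")
    weights = _taper_weights(w, taper_sigma) if taper == "gaussian" else None
    n_windows = (T - w) // s + 1
    starts = np.arange(n_windows) * s
    out = np.empty((n_windows, ts.n_components * (ts.n_components - 1) // 2))
    for m, start in enumerate(starts):
        block = ts.values[:, start:start + w]
        out[m] = fisher_z(_corr_vector(block, weights))
    return WindowedFCSeries(
        values=out,
        window_starts=starts,
        window_length=w,
        slide=s,
        pair_ids=_component_pair_ids(ts.component_ids),
        participant_id=ts.participant_id,
    )
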