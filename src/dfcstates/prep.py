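"""Nuisance processing of component time-courses before FC computation.

The pipeline applied to each participant's component x time matrix is,
in order: despike -> detrend -> confound regression -> band-pass filter.
Despiking is MAD-based winsorization; detrending removes a least-squares
line per component; the band-pass is a zero-phase 4th-order Butterworth
(default 0.01-0.15 Hz).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as _signal

log = logging.getLogger(__name__)

#: scale factor turning a median absolute deviation into a robust SD
MAD_TO_SD = 1.4826


@dataclass(frozen=True)
class ComponentTimecourseSet:
    """One participant's component time-courses.

    Parameters
    ----------
    values : ndarray, shape (n_components, n_timepoints)
        Signal matrix, one row per ICA component.
    tr : float
        Sampling interval (repetition time) in seconds.
    component_ids : tuple of str
        Ordered component labels; identical across a cohort.
    participant_id : str
    """

    values: np.ndarray
    tr: float
    component_ids: tuple
    participant_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be 2-D (components x timepoints)")
        if len(self.component_ids) != v.shape[0]:
            raise ValueError("component_ids length does not match values rows")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite values in time-courses")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "component_ids", tuple(self.component_ids))

    @property
    def n_components(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.tr)


def detrend(ts: ComponentTimecourseSet) -> ComponentTimecourseSet:
    """Remove the per-component least-squares line (intercept + slope)."""
    T = ts.n_timepoints
    if T < 3:
        raise ValueError("detrend needs at least 3 timepoints")
    t = np.arange(T, dtype=float)
    X = np.column_stack([np.ones(T), t])
    beta, *_ = np.linalg.lstsq(X, ts.values.T, rcond=None)
    resid = ts.values - (X @ beta).T
    return replace(ts, values=resid)


def despike(ts: ComponentTimecourseSet, c: float = 4.0) -> ComponentTimecourseSet:
    """Winsorize samples beyond ``c`` robust SDs from the per-component median.

    The robust SD is 1.4826 * MAD.  Components with MAD = 0 (constant or
    near-constant series) are returned unchanged.
    """
    if c <= 0:
        raise ValueError("MAD multiplier c must be positive")
    v = ts.values.copy()
    med = np.median(v, axis=1, keepdims=True)
    mad = np.median(np.abs(v - med), axis=1, keepdims=True)
    robust_sd = MAD_TO_SD * mad
    # rows with zero scale pass through unchanged
    ok = (robust_sd[:, 0] > 0)
    lo = med - c * robust_sd
    hi = med + c * robust_sd
    v[ok] = np.clip(v[ok], lo[ok], hi[ok])
    return replace(ts, values=v)


def regress_confounds(
    ts: ComponentTimecourseSet, confounds: np.ndarray
) -> ComponentTimecourseSet:
    """Regress out confound time series (e.g. realignment parameters).

    ``confounds`` is timepoints x q; an intercept is always included.
    Rank-deficient confound matrices have their dependent columns dropped
    with a warning.  Residuals are orthogonal to every retained column.
    """
    C = np.atleast_2d(np.asarray(confounds, dtype=float))
    if C.shape[0] != ts.n_timepoints:
        if C.shape[1] == ts.n_timepoints:
            C = C.T
        else:
            raise ValueError("confound rows must align with timepoints")
    X = np.column_stack([np.ones(ts.n_timepoints), C])
    # drop linearly dependent columns via QR with pivoting behaviour of lstsq
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        keep = [0]
        for j in range(1, X.shape[1]):
            trial = X[:, keep + [j]]
            if np.linalg.matrix_rank(trial) > len(keep):
                keep.append(j)
        log.warning(
            "confound matrix rank-deficient: dropping %d dependent column(s)",
            X.shape[1] - len(keep),
        )
        X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, ts.values.T, rcond=None)
    resid = ts.values - (X @ beta).T
    return replace(ts, values=resid)


def bandpass(
    ts: ComponentTimecourseSet,
    f_lo: float = 0.01,
    f_hi: float = 0.15,
    order: int = 4,
    pad_len: int = 22,
) -> ComponentTimecourseSet:
    """Zero-phase Butterworth band-pass filter.

    A 4th-order Butterworth is applied forward and backward (``filtfilt``)
    so the effective attenuation is the squared magnitude response and the
    phase is zero.  Edges are handled by reflection padding of ``pad_len``
    samples (one sliding-window length by default).
    """
    nyq = ts.nyquist
    if not (0 <= f_lo < f_hi):
        raise ValueError("need 0 <= f_lo < f_hi")
    if f_hi >= nyq:
        raise ValueError(
            f"f_hi={f_hi} Hz is at/above Nyquist {nyq:.4f} Hz for TR={ts.tr}"
        )
    if f_lo == 0:
        b, a = _signal.butter(order, f_hi / nyq, btype="lowpass")
    else:
        b, a = _signal.butter(order, [f_lo / nyq, f_hi / nyq], btype="bandpass")
    padlen = min(pad_len, ts.n_timepoints - 1)
    filt = _signal.filtfilt(b, a, ts.values, axis=1, padtype="even", padlen=padlen)
    return replace(ts, values=filt)


def preprocess(
    ts: ComponentTimecourseSet,
    confounds: np.ndarray | None = None,
    despike_c: float = 4.0,
    f_lo: float = 0.01,
    f_hi: float = 0.15,
) -> ComponentTimecourseSet:
    """Full nuisance pipeline: despike -> detrend -> confounds -> band-pass."""
    out = despike(ts, c=despike_c)
    out = detrend(out)
    if confounds is not None:
        out = regress_confounds(out, confounds)
    out = bandpass(out, f_lo=f_lo, f_hi=f_hi)
    log.info(
        "prep %s: despike(c=%g) -> detrend -> %s -> bandpass(%g-%g Hz)",
        ts.participant_id, despike_c,
        "confound regression" if confounds is not None else "no confounds",
        f_lo, f_hi,
    )
    return out
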