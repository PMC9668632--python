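"""Permutation tests, family-structured FDR, rank statistics.

The statistical battery: label-permutation two-sample T-tests (Welch
statistic, add-one p-value) for mass-univariate FC comparisons; Cohen's d;
Benjamini-Hochberg FDR applied independently within declared test
families; age residualization; Kruskal-Wallis omnibus and Dunn's post-hoc
rank tests; and age-controlled Spearman partial correlations.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# two-sample permutation T
# --------------------------------------------------------------------------

def _welch_t(x_sum, x_sq, n1, y_sum, y_sq, n2):
    """Welch T from sufficient statistics (vectorized over leading dims)."""
    m1, m2 = x_sum / n1, y_sum / n2
    v1 = (x_sq - n1 * m1**2) / (n1 - 1)
    v2 = (y_sq - n2 * m2**2) / (n2 - 1)
    se = np.sqrt(v1 / n1 + v2 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / se
    return t


def permutation_t_test(
    x: np.ndarray, y: np.ndarray, n_perm: int = 9999, seed: int = 0
) -> tuple[float, float]:
    """Two-sample T-test with a label-permutation null.

    The statistic is the Welch (unequal-variance) T on the observed labels;
    the two-sided p-value is (1 + #{|T*| >= |T_obs|}) / (1 + n_perm) over
    uniformly random label permutations.  Zero variance in both groups
    returns T = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if x.std() == 0 and y.std() == 0:
        log.warning("zero variance in both groups; returning T=0, p=1")
        return 0.0, 1.0
    t_obs, p = mass_permutation_t(x[:, None], y[:, None], n_perm=n_perm, seed=seed)
    return float(t_obs[0]), float(p[0])


def mass_permutation_t(
    X: np.ndarray, Y: np.ndarray, n_perm: int = 9999, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized permutation Welch T over many features at once.

    ``X`` is n1 x m (group 1), ``Y`` n2 x m.  Returns per-feature
    ``(T_obs, p)`` with the add-one two-sided permutation p-value.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n1, m = X.shape
    n2 = Y.shape[0]
    pooled = np.concatenate([X, Y], axis=0)
    pooled_sq = pooled**2
    tot_sum = pooled.sum(axis=0)
    tot_sq = pooled_sq.sum(axis=0)

    t_obs = _welch_t(X.sum(0), (X**2).sum(0), n1, Y.sum(0), (Y**2).sum(0), n2)
    t_obs = np.nan_to_num(t_obs, nan=0.0)

    rng = np.random.default_rng(seed)
    n = n1 + n2
    # permutation indicator matrix for group 1 membership
    G = np.zeros((n_perm, n))
    for r in range(n_perm):
        G[r, rng.permutation(n)[:n1]] = 1.0
    s1 = G @ pooled          # n_perm x m
    q1 = G @ pooled_sq
    t_perm = _welch_t(s1, q1, n1, tot_sum - s1, tot_sq - q1, n2)
    t_perm = np.nan_to_num(t_perm, nan=0.0)
    exceed = (np.abs(t_perm) >= np.abs(t_obs)[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + n_perm)
    return t_obs, p


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d: (mean_x - mean_y) / pooled SD with (n1-1, n2-1) weights."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    v = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) \
        / (x.size + y.size - 2)
    if v == 0:
        raise ValueError("zero pooled SD")
    return float((x.mean() - y.mean()) / np.sqrt(v))


# --------------------------------------------------------------------------
# FDR within declared families
# --------------------------------------------------------------------------

def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_family_correction(results: pd.DataFrame) -> pd.DataFrame:
    """BH-adjust p-values independently within each declared family.

    ``results`` must have columns ``family`` and ``p``; a row with a
    missing family id is an orphan and raises.  Returns a copy with a
    ``p_fdr`` column; family sizes are logged.
    """
    if results["family"].isna().any():
        orphans = results.index[results["family"].isna()].tolist()
        raise ValueError(f"orphan tests without a family: {orphans}")
    out = results.copy()
    out["p_fdr"] = np.nan
    for fam, idx in results.groupby("family").groups.items():
        out.loc[idx, "p_fdr"] = bh_fdr(results.loc[idx, "p"].to_numpy())
    sizes = results["family"].value_counts()
    log.info("FDR families: %d (sizes %s..%s)", len(sizes),
             sizes.min(), sizes.max())
    return out


# --------------------------------------------------------------------------
# rank-based tests after age residualization
# --------------------------------------------------------------------------

def age_residuals(values: np.ndarray, age: np.ndarray) -> np.ndarray:
    """Residuals of the least-squares regression of values on (1, age)."""
    values = np.asarray(values, dtype=float)
    age = np.asarray(age, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 participants")
    if np.ptp(age) == 0:
        raise ValueError("age is constant; residualization undefined")
    X = np.column_stack([np.ones(age.size), age])
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    return values - X @ beta


def kruskal_wallis(*groups) -> tuple[float, int, float]:
    """Kruskal-Wallis H with tie correction; returns (H, df, p)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrs):
        raise ValueError("each group needs n >= 2")
    pooled = np.concatenate(arrs)
    if np.ptp(pooled) == 0:
        raise ValueError("all values identical; H undefined")
    h, p = _st.kruskal(*arrs)
    return float(h), len(arrs) - 1, float(p)


def dunns_posthoc(
    groups: dict, family: str = "posthoc"
) -> pd.DataFrame:
    """Dunn's pairwise rank tests with tie correction and BH over the pairs.

    ``groups`` maps group name to a 1-D sample.  Z follows the sign
    convention Z(a, b) = -Z(b, a) with a, b in insertion order.  Returns a
    tidy frame with columns test_id, family, group1, group2, statistic
    (Z), p, p_fdr, n1, n2.
    """
    names = list(groups)
    arrs = {g: np.asarray(groups[g], dtype=float) for g in names}
    pooled = np.concatenate([arrs[g] for g in names])
    if np.ptp(pooled) == 0:
        raise ValueError("all values identical")
    N = pooled.size
    ranks = _st.rankdata(pooled)
    mean_rank = {}
    off = 0
    for g in names:
        n = arrs[g].size
        mean_rank[g] = ranks[off:off + n].mean()
        off += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (N - 1))
    var_core = N * (N + 1) / 12.0 - tie_term
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            na, nb = arrs[a].size, arrs[b].size
            se = np.sqrt(var_core * (1.0 / na + 1.0 / nb))
            z = (mean_rank[a] - mean_rank[b]) / se
            p = 2.0 * _st.norm.sf(abs(z))
            rows.append({
                "test_id": f"{a}_vs_{b}", "family": family,
                "group1": a, "group2": b, "statistic": z,
                "p": max(p, np.finfo(float).tiny), "n1": na, "n2": nb,
            })
    df = pd.DataFrame(rows)
    df["p_fdr"] = bh_fdr(df["p"].to_numpy())
    return df


# --------------------------------------------------------------------------
# Spearman partial correlation controlling for age
# --------------------------------------------------------------------------

def _partial_from_ranks(rx, ry, rc):
    X = np.column_stack([np.ones(rc.size), rc])
    bx, *_ = np.linalg.lstsq(X, rx, rcond=None)
    by, *_ = np.linalg.lstsq(X, ry, rcond=None)
    ex, ey = rx - X @ bx, ry - X @ by
    sx, sy = ex.std(), ey.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero variance after ranking/residualization")
    return float(np.clip((ex * ey).mean() / (sx * sy), -1.0, 1.0))


def spearman_partial(
    x: np.ndarray, y: np.ndarray, covariate: np.ndarray
) -> tuple[float, float]:
    """Spearman partial correlation of x and y controlling for a covariate.

    All three variables are rank-transformed, then the Pearson partial
    correlation of the ranks given the rank-covariate is computed.
    Incomplete triples are dropped pairwise.  p is from the t
    approximation with n - 3 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(covariate, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(c)
    x, y, c = x[ok], y[ok], c[ok]
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 complete triples")
    rho = _partial_from_ranks(_st.rankdata(x), _st.rankdata(y), _st.rankdata(c))
    df = n - 3
    if abs(rho) >= 1.0:
        return rho, np.finfo(float).tiny
    t = rho * np.sqrt(df / (1.0 - rho**2))
    p = 2.0 * _st.t.sf(abs(t), df)
    return rho, float(max(p, np.finfo(float).tiny))


def mass_spearman_partial(
    X: np.ndarray, y: np.ndarray, covariate: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized Spearman partial correlation of each column of X with y.

    Rows with a missing y or covariate are dropped; X is assumed complete
    on the remaining rows (FC data).  Returns (rho, p, n).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(covariate, dtype=float)
    ok = np.isfinite(y) & np.isfinite(c) & np.all(np.isfinite(X), axis=1)
    X, y, c = X[ok], y[ok], c[ok]
    n = y.size
    if n < 4:
        raise ValueError("need at least 4 complete rows")
    RX = np.apply_along_axis(_st.rankdata, 0, X)
    ry = _st.rankdata(y)
    rc = _st.rankdata(c)
    M = np.column_stack([np.ones(n), rc])
    # residualize ranks on (1, rank-covariate)
    coefX, *_ = np.linalg.lstsq(M, RX, rcond=None)
    EX = RX - M @ coefX
    by, *_ = np.linalg.lstsq(M, ry, rcond=None)
    ey = ry - M @ by
    sx = EX.std(axis=0)
    sy = ey.std()
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (EX * ey[:, None]).mean(axis=0) / (sx * sy)
    rho = np.clip(np.nan_to_num(rho, nan=0.0), -1.0, 1.0)
    df = n - 3
    with np.errstate(divide="ignore"):
        t = rho * np.sqrt(df / np.maximum(1.0 - rho**2, 1e-300))
    p = np.maximum(2.0 * _st.t.sf(np.abs(t), df), np.finfo(float).tiny)
    return rho, p, n
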