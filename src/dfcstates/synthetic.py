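"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure the analysis assumes: each participant's
component time-courses are piecewise-stationary multivariate normal draws
switching among k latent connectivity states under a first-order Markov
chain, with a group-dependent bias on the occupancy of the last (highest
connectivity) state.  A matching clinical table provides raw test scores
across seven domains, EDSS, age, sex and group labels, with planted
standardized effect sizes between disability subgroups.

The generator emulates state-switching covariance structure and
group/clinical correlations; it does not simulate raw 4D fMRI volumes,
head motion, scanner noise spectra, or ICA mixing.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .networks import NetworkAssignment, default_assignment
from .prep import ComponentTimecourseSet

_SEED_STRIDE = 7919  # fixed per-participant seed offset from the master seed


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

def repair_correlation(C: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix to a valid correlation matrix.

    Eigenvalues are clipped at 0 and the result renormalized to unit
    diagonal; matrices already PSD (within ``tol``) are only symmetrized.
    """
    C = np.asarray(C, dtype=float)
    C = 0.5 * (C + C.T)
    w, V = np.linalg.eigh(C)
    if w.min() < -tol:
        w = np.clip(w, 0.0, None)
        C = (V * w) @ V.T
    d = np.sqrt(np.diag(C))
    if np.any(d <= 0):
        raise ValueError("degenerate correlation matrix after PSD repair")
    C = C / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return 0.5 * (C + C.T)


@dataclass
class StateProcessConfig:
    """Latent connectivity-state process: Markov chain + per-state correlations."""

    k_states: int
    transition_matrix: np.ndarray          # k x k, row stochastic
    centroid_correlations: list            # k matrices, n_comp x n_comp
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_states < 1:
            raise ValueError("k_states must be >= 1")
        P = np.asarray(self.transition_matrix, dtype=float)
        if P.shape != (self.k_states, self.k_states):
            raise ValueError("transition matrix shape must be k x k")
        if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition matrix rows must be stochastic")
        if len(self.centroid_correlations) != self.k_states:
            raise ValueError("need one centroid correlation matrix per state")
        self.transition_matrix = P
        self.centroid_correlations = [
            repair_correlation(C) for C in self.centroid_correlations
        ]
        n = self.centroid_correlations[0].shape[0]
        if any(C.shape != (n, n) for C in self.centroid_correlations):
            raise ValueError("centroid matrices must share one shape")

    @property
    def n_components(self) -> int:
        return self.centroid_correlations[0].shape[0]

    @property
    def dwell_scale(self) -> np.ndarray:
        """Expected run length (in TR) implied by the diagonal, 1/(1-p_stay)."""
        d = np.diag(self.transition_matrix)
        return 1.0 / np.maximum(1.0 - d, 1e-12)


@dataclass
class CohortConfig:
    """Cohort-level generator settings.

    ``group_occupancy_shift`` is added to the last state's self-transition
    probability for the mild-to-moderate disability group, planting a group
    effect on that state's fraction time.  ``clinical_effect_sizes`` are
    standardized mean differences (mild vs no disability) per domain.
    """

    n_hc: int = 101
    n_mild: int = 39
    n_nodis: int = 36
    n_median: int = 17              # patients tied at the median EDSS (1.5)
    n_components: int = 47
    n_timepoints: int = 255
    tr: float = 2.25
    group_occupancy_shift: float = 0.035
    clinical_effect_sizes: dict = field(default_factory=lambda: {
        "vision": 0.7, "motor": 0.8, "fatigue": 1.2, "depression": 0.7,
        "cognition": 0.4, "brain_volume": 0.55, "lesion_load": 0.7,
    })
    missingness_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_hc", "n_mild", "n_nodis"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_median < 0:
            raise ValueError("n_median must be >= 0")
        if not (0 <= self.missingness_rate < 1):
            raise ValueError("missingness_rate must be in [0, 1)")
        if self.tr <= 0:
            raise ValueError("TR must be positive")


# --------------------------------------------------------------------------
# default state process: 5 states over the 8-network component layout
# --------------------------------------------------------------------------

#: default self-transition probabilities; stationary occupancy is
#: proportional to 1/(1 - p_stay) and therefore decreases from state 1 to 5
DEFAULT_STAY = (0.980, 0.975, 0.970, 0.962, 0.950)


def _block_correlation(assignment: NetworkAssignment,
                       within: dict, between: dict,
                       base_within: float, base_between: float) -> np.ndarray:
    ids = assignment.component_ids
    n = len(ids)
    nets = [assignment.network_of(c) for c in ids]
    C = np.empty((n, n))
    for a in range(n):
        for b in range(n):
            if a == b:
                C[a, b] = 1.0
                continue
            na, nb = nets[a], nets[b]
            if na == nb:
                C[a, b] = within.get(na, base_within)
            else:
                key = tuple(sorted((na, nb)))
                C[a, b] = between.get(key, base_between)
    return C


def default_centroids(assignment: NetworkAssignment | None = None) -> list:
    """Five network-structured state correlation matrices.

    State 1 is weakly connected (most frequent), state 5 strongly and
    globally connected (least frequent, lowest modularity); states 2-4
    carry distinct network-specific patterns including anticorrelations.
    """
    if assignment is None:
        assignment = default_assignment()
    specs = [
        # (per-network within, per-pair between, base within, base between)
        # state 1: globally weak, mildly segregated (most frequent)
        ({n: 0.15 for n in ("vATT", "dATT", "SMN", "DMN", "VIS", "FPN", "CB")},
         {("DMN", "dATT"): 0.35, ("SMN", "vATT"): -0.40, ("FPN", "SMN"): 0.35,
          ("VIS", "dATT"): -0.35, ("DMN", "VIS"): -0.30}, 0.15, 0.02),
        # state 2: sensory-dominant (VIS+SMN) with DMN decoupling
        ({"VIS": 0.80, "SMN": 0.80},
         {("SMN", "VIS"): 0.60, ("DMN", "FPN"): -0.40, ("DMN", "VIS"): -0.40,
          ("DMN", "SMN"): -0.35, ("SMN", "dATT"): 0.45,
          ("VIS", "dATT"): 0.40}, 0.25, 0.10),
        # state 3: DMN/FPN-dominant with sensory decoupling
        ({"DMN": 0.80, "FPN": 0.80},
         {("DMN", "FPN"): 0.60, ("DMN", "SMN"): 0.40, ("FPN", "VIS"): -0.40,
          ("SMN", "VIS"): -0.40, ("DMN", "VIS"): 0.35, ("SMN", "dATT"): -0.35,
          ("FPN", "SMN"): 0.40}, 0.25, 0.10),
        # state 4: attention-dominant, DMN anticorrelated
        ({"dATT": 0.80, "vATT": 0.80},
         {("dATT", "vATT"): 0.60, ("DMN", "dATT"): -0.40, ("DMN", "VIS"): 0.40,
          ("SMN", "vATT"): 0.45, ("DMN", "SMN"): -0.40, ("FPN", "VIS"): 0.40,
          ("SMN", "VIS"): 0.30, ("FPN", "SMN"): -0.35,
          ("VIS", "dATT"): -0.35}, 0.25, 0.10),
        # state 5: globally hyperconnected (least frequent, lowest modularity)
        ({}, {}, 0.55, 0.28),
    ]
    return [
        repair_correlation(_block_correlation(assignment, w, b, bw, bb))
        for (w, b, bw, bb) in specs
    ]


def default_state_process(
    assignment: NetworkAssignment | None = None,
    stay: tuple = DEFAULT_STAY,
    seed: int = 0,
) -> StateProcessConfig:
    """Default 5-state process over the 47-component layout."""
    if assignment is None:
        assignment = default_assignment()
    k = len(stay)
    P = transition_matrix_from_stay(np.asarray(stay, dtype=float))
    return StateProcessConfig(
        k_states=k,
        transition_matrix=P,
        centroid_correlations=default_centroids(assignment),
        seed=seed,
    )


def transition_matrix_from_stay(stay: np.ndarray) -> np.ndarray:
    """Row-stochastic matrix with given diagonal and uniform off-diagonals."""
    stay = np.asarray(stay, dtype=float)
    if np.any(stay >= 1) or np.any(stay < 0):
        raise ValueError("stay probabilities must be in [0, 1)")
    k = stay.shape[0]
    P = np.full((k, k), 0.0)
    for i in range(k):
        off = (1.0 - stay[i]) / (k - 1) if k > 1 else 0.0
        P[i] = off
        P[i, i] = stay[i] if k > 1 else 1.0
    return P


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix.

    Falls back to uniform when the stationary vector is not unique
    (reducible or periodic chains).
    """
    P = np.asarray(P, dtype=float)
    k = P.shape[0]
    w, V = np.linalg.eig(P.T)
    close = np.flatnonzero(np.abs(w - 1.0) < 1e-9)
    if close.size != 1:
        return np.full(k, 1.0 / k)
    pi = np.real(V[:, close[0]])
    pi = np.abs(pi)
    return pi / pi.sum()


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------

def generate_state_sequence(
    cfg: StateProcessConfig,
    n_windows: int,
    seed: int,
    start_state: int | None = None,
) -> np.ndarray:
    """Markov state-label sequence of length ``n_windows``, labels 1..k.

    The first label is drawn from the stationary distribution of the
    transition matrix (uniform fallback when it is not unique) unless
    ``start_state`` (1-based) forces it.
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    P = cfg.transition_matrix
    k = cfg.k_states
    rng = np.random.default_rng(seed)
    cum = np.cumsum(P, axis=1)
    labels = np.empty(n_windows, dtype=int)
    if start_state is None:
        pi = stationary_distribution(P)
        labels[0] = rng.choice(k, p=pi)
    else:
        labels[0] = start_state - 1
    u = rng.random(n_windows - 1)
    for t in range(1, n_windows):
        labels[t] = np.searchsorted(cum[labels[t - 1]], u[t - 1], side="right")
    return labels + 1


def generate_timecourses(
    cfg: StateProcessConfig,
    cohort: CohortConfig,
    participant_seed: int,
    participant_id: str = "",
) -> tuple[ComponentTimecourseSet, np.ndarray]:
    """One participant's component time-courses plus per-TR truth labels.

    Each TR is a zero-mean multivariate normal draw whose correlation
    matrix is the current state's centroid.
    """
    n_comp = cfg.n_components
    if n_comp != cohort.n_components:
        raise ValueError("state process and cohort disagree on n_components")
    T = cohort.n_timepoints
    labels = generate_state_sequence(cfg, T, seed=participant_seed)
    rng = np.random.default_rng(participant_seed + 1)
    chols = [np.linalg.cholesky(C + 1e-10 * np.eye(n_comp))
             for C in cfg.centroid_correlations]
    z = rng.standard_normal((T, n_comp))
    X = np.empty((T, n_comp))
    for s in range(cfg.k_states):
        idx = labels == s + 1
        if idx.any():
            X[idx] = z[idx] @ chols[s].T
    ids = tuple(f"IC{i + 1:02d}" for i in range(n_comp))
    ts = ComponentTimecourseSet(
        values=X.T, tr=cohort.tr, component_ids=ids,
        participant_id=participant_id,
    )
    return ts, labels


def shifted_state_process(cfg: StateProcessConfig, shift: float) -> StateProcessConfig:
    """Copy of ``cfg`` with the last state's stay probability raised by ``shift``."""
    P = cfg.transition_matrix.copy()
    k = cfg.k_states
    i = k - 1
    new_stay = P[i, i] + shift
    if not (0 <= new_stay < 1):
        raise ValueError("occupancy shift pushes stay probability out of [0, 1)")
    off = (1.0 - new_stay) / (k - 1) if k > 1 else 0.0
    P[i] = off
    P[i, i] = new_stay
    return StateProcessConfig(
        k_states=k, transition_matrix=P,
        centroid_correlations=[C.copy() for C in cfg.centroid_correlations],
        seed=cfg.seed,
    )


# ----- clinical battery ----------------------------------------------------

# (test name, domain); direction handling follows the domain recoding rule:
# raw scores for vision/cognition/brain_volume run "higher = better", all
# others "higher = worse".
CLINICAL_TESTS: tuple = tuple(
    [(f"ETDRS100_{eye}_{m}", "vision")
     for eye in ("R", "L") for m in ("acuity", "letters")]
    + [(f"ETDRS10_{eye}_{m}", "vision")
       for eye in ("R", "L") for m in ("acuity", "letters")]
    + [(f"Sloan2.5_{eye}_{m}", "vision")
       for eye in ("R", "L") for m in ("acuity", "letters")]
    + [(f"Sloan1.25_{eye}_{m}", "vision")
       for eye in ("R", "L") for m in ("acuity", "letters")]
    + [("T25FW", "motor"), ("NHPT", "motor")]
    + [("FSS", "fatigue"), ("BDI_II", "depression")]
    + [("SRT_LTS", "cognition"), ("SRT_CLTR", "cognition"),
       ("SRT_DR", "cognition"), ("SPAT", "cognition"),
       ("SPAT_DR", "cognition"), ("SDMT", "cognition"),
       ("PASAT", "cognition"), ("WLG", "cognition")]
    + [("NBV", "brain_volume"), ("T2LV", "lesion_load")]
)

#: domains whose raw test scores run "higher = better" and are therefore
#: recoded by -1 at the composite stage
RECODE_DOMAINS = ("vision", "cognition", "brain_volume")

#: plausible raw scales (mean, SD) per test so the table looks like real data
_RAW_SCALES = {
    "T25FW": (5.0, 1.2), "NHPT": (20.0, 3.5), "FSS": (3.5, 1.4),
    "BDI_II": (8.0, 6.0), "SDMT": (55.0, 10.0), "PASAT": (45.0, 9.0),
    "WLG": (25.0, 6.0), "NBV": (1550.0, 80.0), "T2LV": (3.0, 3.0),
}

_EDSS_MILD_GRID = (2.0, 2.5, 3.0, 3.5, 4.0, 5.5)
_EDSS_MILD_PROBS = (0.33, 0.30, 0.18, 0.12, 0.05, 0.02)


def generate_clinical_cohort(cohort: CohortConfig) -> pd.DataFrame:
    """Demographics, EDSS and raw clinical test scores for the whole cohort.

    Healthy controls carry no EDSS or clinical scores (as in typical
    patient-only batteries).  Patient subgroups: ``n_nodis`` with EDSS in
    {0, 1}, ``n_mild`` with EDSS >= 2, ``n_median`` tied at EDSS 1.5.  Age
    is drawn older in the higher-EDSS subgroup.  Raw scores are drawn with
    subgroup mean shifts equal to ``clinical_effect_sizes`` (in SD units),
    oriented so the impairment-coded composite is higher in the disability
    group.  Missing entries are inserted at ``missingness_rate``.
    """
    rng = np.random.default_rng(cohort.seed)
    rows = []
    pid = 0

    def base_row(group, subgroup, age_mu, age_sd):
        nonlocal pid
        pid += 1
        return {
            "participant_id": f"P{pid:04d}",
            "group": group,
            "subgroup": subgroup,
            "age": float(np.clip(rng.normal(age_mu, age_sd), 18, 75)),
            "sex": "F" if rng.random() < 0.66 else "M",
        }

    for _ in range(cohort.n_hc):
        r = base_row("HC", "HC", 35.0, 10.3)
        r["EDSS"] = np.nan
        rows.append(r)
    for _ in range(cohort.n_nodis):
        r = base_row("MS", "no_disability", 31.6, 6.1)
        r["EDSS"] = float(rng.choice([0.0, 1.0], p=[0.35, 0.65]))
        rows.append(r)
    for _ in range(cohort.n_median):
        r = base_row("MS", "median_tied", 36.0, 10.0)
        r["EDSS"] = 1.5
        rows.append(r)
    for _ in range(cohort.n_mild):
        r = base_row("MS", "mild_moderate", 40.2, 11.6)
        r["EDSS"] = float(rng.choice(_EDSS_MILD_GRID, p=_EDSS_MILD_PROBS))
        rows.append(r)

    df = pd.DataFrame(rows)
    is_ms = (df["group"] == "MS").to_numpy()
    is_mild = (df["subgroup"] == "mild_moderate").to_numpy()

    for test, domain in CLINICAL_TESTS:
        es = cohort.clinical_effect_sizes.get(domain, 0.0)
        # impairment direction: higher-is-better tests shift DOWN in the
        # disability group
        sign = -1.0 if domain in RECODE_DOMAINS else 1.0
        z = rng.standard_normal(len(df))
        z[is_mild] += sign * es
        mu, sd = _RAW_SCALES.get(test, (50.0, 10.0))
        raw = mu + sd * z
        raw[~is_ms] = np.nan
        if cohort.missingness_rate > 0:
            miss = is_ms & (rng.random(len(df)) < cohort.missingness_rate)
            raw[miss] = np.nan
        df[test] = raw
    return df


def generate_cohort(
    cohort: CohortConfig,
    state_cfg: StateProcessConfig | None = None,
    with_timecourses: bool = True,
):
    """Full desk-scale cohort: clinical table, time-courses, truth labels.

    Returns ``(manifest, timecourses, truth_labels)`` where ``manifest`` is
    the clinical/demographic DataFrame (with a per-participant seed column),
    ``timecourses`` maps participant id to :class:`ComponentTimecourseSet`
    and ``truth_labels`` maps participant id to the per-TR state sequence.
    The mild-disability group's state process carries the configured
    occupancy shift on the last state.
    """
    if state_cfg is None:
        state_cfg = default_state_process(
            default_assignment(cohort.n_components))
    manifest = generate_clinical_cohort(cohort)
    manifest["seed"] = [
        (cohort.seed + _SEED_STRIDE * (i + 1)) % (2**31)
        for i in range(len(manifest))
    ]
    timecourses: dict = {}
    truth: dict = {}
    if with_timecourses:
        shifted = shifted_state_process(state_cfg, cohort.group_occupancy_shift)
        for _, row in manifest.iterrows():
            cfg = shifted if row["subgroup"] == "mild_moderate" else state_cfg
            ts, labels = generate_timecourses(
                cfg, cohort, int(row["seed"]), participant_id=row["participant_id"])
            timecourses[row["participant_id"]] = ts
            truth[row["participant_id"]] = labels
    return manifest, timecourses, truth


def window_truth_labels(tr_labels: np.ndarray, w: int = 22, s: int = 1) -> np.ndarray:
    """Ground-truth window labels by majority vote over each window's TRs."""
    T = tr_labels.shape[0]
    n_windows = (T - w) // s + 1
    out = np.empty(n_windows, dtype=int)
    for m in range(n_windows):
        seg = tr_labels[m * s:m * s + w]
        vals, counts = np.unique(seg, return_counts=True)
        out[m] = vals[np.argmax(counts)]  # ties -> lowest label
    return out
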