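"""Temporal state metrics, state-wise connectivity/topology, and ASOC.

Temporal metrics summarize a participant's per-window state-label
sequence: fraction time (fractional occupancy), mean dwell time (mean run
length), transition counts between pairs of distinct states, and
stickiness (number of adjacent window pairs spent in the same state).
State-wise summaries are the global mean Fisher-Z connectivity over the
windows spent in a state and the modularity Q of the participant's
median per-state FC matrix under a community-Louvain partition with a
signed (asymmetric) null.  Across-state overall connectivity (ASOC)
averages all windowed FC values irrespective of state, at the grand,
intra-network and inter-network scale.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import FCVector, WindowedFCSeries, devectorize
from .networks import NetworkAssignment


# --------------------------------------------------------------------------
# temporal metrics on label sequences (labels 1..k)
# --------------------------------------------------------------------------

def _runs(labels: np.ndarray):
    """Yield (state, run_length) for maximal runs."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [labels.size]])
    for a, b in zip(starts, ends):
        yield int(labels[a]), int(b - a)


def fraction_time(labels: np.ndarray, k: int) -> np.ndarray:
    """Proportion of windows spent in each state; unvisited states get 0."""
    labels = np.asarray(labels)
    if labels.size < 1:
        raise ValueError("need at least 1 window")
    return np.array([(labels == s).sum() for s in range(1, k + 1)],
                    dtype=float) / labels.size


def mean_dwell_time(labels: np.ndarray, k: int) -> np.ndarray:
    """Mean run length (in windows) per state; NaN when never visited."""
    labels = np.asarray(labels)
    if labels.size < 1:
        raise ValueError("need at least 1 window")
    sums = np.zeros(k)
    counts = np.zeros(k)
    for s, length in _runs(labels):
        sums[s - 1] += length
        counts[s - 1] += 1
    out = np.full(k, np.nan)
    vis = counts > 0
    out[vis] = sums[vis] / counts[vis]
    return out


def n_runs(labels: np.ndarray, k: int) -> np.ndarray:
    """Number of maximal runs per state."""
    counts = np.zeros(k, dtype=int)
    for s, _ in _runs(labels):
        counts[s - 1] += 1
    return counts


def transition_counts(labels: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Ordered and unordered switch counts between distinct states.

    Returns ``(ordered, unordered)``: ``ordered[a-1, b-1]`` counts
    positions t with label_t = a, label_{t+1} = b (a != b, zero diagonal);
    ``unordered`` is its symmetrization (a->b plus b->a).
    """
    labels = np.asarray(labels)
    if labels.size < 2:
        raise ValueError("need at least 2 windows")
    ordered = np.zeros((k, k), dtype=int)
    a, b = labels[:-1], labels[1:]
    switch = a != b
    for x, y in zip(a[switch], b[switch]):
        ordered[x - 1, y - 1] += 1
    return ordered, ordered + ordered.T


def stickiness(labels: np.ndarray, k: int) -> np.ndarray:
    """Adjacent same-state window pairs, attributed to that state."""
    labels = np.asarray(labels)
    if labels.size < 2:
        raise ValueError("need at least 2 windows")
    out = np.zeros(k, dtype=int)
    stay = labels[:-1] == labels[1:]
    for s in labels[:-1][stay]:
        out[s - 1] += 1
    return out


def state_average_connectivity(
    wfc: WindowedFCSeries | np.ndarray, labels: np.ndarray, k: int
) -> np.ndarray:
    """Global mean Fisher-Z over all pairs and windows per state; NaN if unvisited."""
    V = wfc.values if isinstance(wfc, WindowedFCSeries) else np.asarray(wfc)
    labels = np.asarray(labels)
    if labels.shape[0] != V.shape[0]:
        raise ValueError("labels misaligned with windows")
    out = np.full(k, np.nan)
    for s in range(1, k + 1):
        mask = labels == s
        if mask.any():
            out[s - 1] = float(V[mask].mean())
    return out


# --------------------------------------------------------------------------
# community Louvain with a signed (asymmetric) modularity
# --------------------------------------------------------------------------

def modularity_signed(W: np.ndarray, labels: np.ndarray, gamma: float = 1.0) -> float:
    """Signed modularity Q of a partition.

    Positive and negative weight layers contribute asymmetrically:
    Q = Q+/v+  -  Q-/(v+ + v-), where Q+- are the within-community excess
    weights of each layer against its degree-matched null and v+- the
    layer's total weight.
    """
    W = np.asarray(W, dtype=float)
    labels = np.asarray(labels)
    Wp = np.clip(W, 0, None)
    Wn = np.clip(-W, 0, None)
    same = labels[:, None] == labels[None, :]

    def layer(Wl):
        v = Wl.sum()
        if v == 0:
            return 0.0, 0.0
        kl = Wl.sum(axis=1)
        q = Wl[same].sum() - gamma * (np.outer(kl, kl)[same].sum()) / v
        return q, v

    qp, vp = layer(Wp)
    qn, vn = layer(Wn)
    Q = 0.0
    if vp > 0:
        Q += qp / vp
    if vn > 0:
        Q -= qn / (vp + vn)
    return float(Q)


def _louvain_one_level(W: np.ndarray, gamma: float, rng) -> np.ndarray:
    """One Louvain pass of local moves on a (possibly aggregated) signed graph."""
    n = W.shape[0]
    Wp = np.clip(W, 0, None)
    Wn = np.clip(-W, 0, None)
    kp, kn = Wp.sum(1), Wn.sum(1)
    vp, vn = Wp.sum(), Wn.sum()
    labels = np.arange(n)
    Sp = kp.copy()  # per-community total positive strength
    Sn = kn.copy()
    # asymmetric layer weights in the gain
    ap = 1.0 / vp if vp > 0 else 0.0
    an = 1.0 / (vp + vn) if vn > 0 else 0.0
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            a = labels[i]
            # neighbour strengths into each community (excluding self-loop)
            wp_i = Wp[i].copy(); wp_i[i] = 0.0
            wn_i = Wn[i].copy(); wn_i[i] = 0.0
            to_p = np.bincount(labels, weights=wp_i, minlength=n)
            to_n = np.bincount(labels, weights=wn_i, minlength=n)
            Sp[a] -= kp[i]
            Sn[a] -= kn[i]

            def gain(c):
                g = 0.0
                if vp > 0:
                    g += ap * (to_p[c] - gamma * kp[i] * Sp[c] / vp)
                if vn > 0:
                    g -= an * (to_n[c] - gamma * kn[i] * Sn[c] / vn)
                return g

            cand = np.unique(np.concatenate(
                [labels[(wp_i > 0) | (wn_i > 0)], [a]]))
            gains = {c: gain(c) for c in cand}
            best = max(sorted(gains), key=lambda c: gains[c])
            if gains[best] <= gains[a] + 1e-15:
                best = a
            labels[i] = best
            Sp[best] += kp[i]
            Sn[best] += kn[i]
            if best != a:
                improved = True
    # compact labels
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def _aggregate(W: np.ndarray, labels: np.ndarray) -> np.ndarray:
    m = labels.max() + 1
    B = np.zeros((labels.size, m))
    B[np.arange(labels.size), labels] = 1.0
    return B.T @ W @ B


def modularity_louvain(
    fc: FCVector | np.ndarray,
    gamma: float = 1.0,
    negative_weight_rule: str = "asym",
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[float, np.ndarray]:
    """Community Louvain on a signed weighted FC graph.

    ``fc`` may be an :class:`FCVector` (devectorized to the symmetric
    matrix with zero diagonal) or a square matrix.  Negative weights are
    handled per ``negative_weight_rule``: ``"asym"`` (signed, asymmetric
    null; default), ``"abs"`` (cluster on |W|) or ``"zero"`` (clip
    negatives to 0).  The node-visit order is shuffled per restart
    (seeded); the best-Q partition of ``n_restarts`` is returned.

    Returns ``(Q, partition)`` with Q always evaluated under the signed
    asymmetric definition on the rule-transformed matrix.
    """
    if isinstance(fc, FCVector):
        W = fc.as_matrix(diag=0.0)
    else:
        W = np.asarray(fc, dtype=float)
        if W.ndim == 1:
            W = devectorize(W, diag=0.0)
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("weight matrix must be symmetric")
    if negative_weight_rule == "abs":
        W = np.abs(W)
    elif negative_weight_rule == "zero":
        W = np.clip(W, 0, None)
    elif negative_weight_rule != "asym":
        raise ValueError(f"unknown negative weight rule {negative_weight_rule!r}")
    if np.all(W == 0):
        raise ValueError("all-zero weight matrix")
    n = W.shape[0]
    best_q, best_part = -np.inf, None
    for r in range(n_restarts):
        rng = np.random.default_rng(seed + r)
        labels = np.arange(n)
        Wl = W.copy()
        while True:
            sub = _louvain_one_level(Wl, gamma, rng)
            if sub.max() + 1 == Wl.shape[0]:
                break
            labels = sub[labels]
            Wl = _aggregate(Wl, sub)
        q = modularity_signed(W, labels, gamma=gamma)
        if q > best_q:
            best_q, best_part = q, labels.copy()
    return best_q, best_part


# --------------------------------------------------------------------------
# across-state overall connectivity (ASOC)
# --------------------------------------------------------------------------

@dataclass
class ASOCTable:
    """One participant's overall-connectivity averages.

    ``grand`` is the mean over all pairs and windows; ``intra[N]`` the mean
    over pairs with both components in network N (only networks with >= 2
    components); ``inter[N]`` the mean over pairs with exactly one
    component in N (all networks); ``pairwise[(N, M)]`` the mean over pairs
    spanning networks N and M.
    """

    participant_id: str
    grand: float
    intra: dict = field(default_factory=dict)
    inter: dict = field(default_factory=dict)
    pairwise: dict = field(default_factory=dict)


def _pair_networks(pair_ids, assignment: NetworkAssignment):
    missing = assignment.check_covers(
        sorted({c for pair in pair_ids for c in pair}))
    if missing:
        raise ValueError(f"components missing from assignment: {missing}")
    netA = np.array([assignment.network_of(i) for i, _ in pair_ids])
    netB = np.array([assignment.network_of(j) for _, j in pair_ids])
    return netA, netB


def asoc(
    wfc: WindowedFCSeries, assignment: NetworkAssignment
) -> ASOCTable:
    """Across-state overall connectivity from all windows of one participant."""
    for net in assignment.networks:
        if assignment.size(net) == 0:  # defensive; mapping can't produce this
            raise ValueError(f"network {net} has no components")
    netA, netB = _pair_networks(wfc.pair_ids, assignment)
    pair_means = wfc.values.mean(axis=0)  # mean over windows per pair
    grand = float(pair_means.mean())
    intra, inter, pairwise = {}, {}, {}
    for net in assignment.networks:
        in_a, in_b = netA == net, netB == net
        if assignment.size(net) >= 2:
            both = in_a & in_b
            intra[net] = float(pair_means[both].mean())
        one = in_a ^ in_b
        inter[net] = float(pair_means[one].mean())
    nets = assignment.networks
    for x in range(len(nets)):
        for y in range(x + 1, len(nets)):
            a, b = nets[x], nets[y]
            span = ((netA == a) & (netB == b)) | ((netA == b) & (netB == a))
            if span.any():
                pairwise[(a, b)] = float(pair_means[span].mean())
    return ASOCTable(participant_id=wfc.participant_id, grand=grand,
                     intra=intra, inter=inter, pairwise=pairwise)


def static_overall_connectivity(
    fc: FCVector, assignment: NetworkAssignment
) -> ASOCTable:
    """ASOC-shaped table from the static FC vector (a single 'window')."""
    one = WindowedFCSeries(
        values=fc.values[None, :], window_starts=np.array([0]),
        window_length=0, slide=1, pair_ids=fc.pair_ids,
        participant_id=fc.participant_id,
    )
    return asoc(one, assignment)
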