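"""Model/Results interface over the dynamic-FC pipeline.

:class:`DynamicFCModel` is built from a cohort of component time-courses
plus a network assignment; :meth:`DynamicFCModel.fit` runs nuisance prep,
static and sliding-window FC, state clustering (with k selection when k is
not fixed), occupancy re-coding, per-state medians, temporal metrics,
modularity and ASOC, and returns a :class:`DynamicFCResults` carrying the
estimates and diagnostics with a ``summary()`` table.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import connectivity as _conn
from . import metrics as _metrics
from . import prep as _prep
from . import states as _states
from .networks import NetworkAssignment, default_assignment


class DynamicFCModel:
    """Dynamic functional-connectivity state model for a cohort.

    Parameters
    ----------
    timecourses : dict
        participant id -> :class:`ComponentTimecourseSet`.
    assignment : NetworkAssignment, optional
        Component-to-network map; defaults to the 8-network layout.
    window, slide : int
        Sliding-window length and step in TR (defaults 22 and 1).
    taper : None or "gaussian"
        Optional window taper (rectangle convolved with a Gaussian).
    do_prep : bool
        Apply despike/detrend/band-pass nuisance processing before FC.
    """

    def __init__(
        self,
        timecourses: dict,
        assignment: NetworkAssignment | None = None,
        window: int = 22,
        slide: int = 1,
        taper: str | None = None,
        do_prep: bool = True,
        band: tuple = (0.01, 0.15),
        despike_c: float = 4.0,
        manifest: pd.DataFrame | None = None,
    ):
        if not timecourses:
            raise ValueError("empty cohort")
        first = next(iter(timecourses.values()))
        ids = first.component_ids
        for p, ts in timecourses.items():
            if ts.component_ids != ids:
                raise ValueError(f"component ordering differs for {p}")
        self.timecourses = dict(timecourses)
        self.assignment = assignment or default_assignment(len(ids))
        missing = self.assignment.check_covers(list(ids))
        if missing:
            raise ValueError(f"components not in assignment: {missing}")
        self.window = int(window)
        self.slide = int(slide)
        self.taper = taper
        self.do_prep = do_prep
        self.band = band
        self.despike_c = despike_c
        self.manifest = manifest

    @classmethod
    def from_synthetic(cls, cohort_config, state_config=None, **kwargs):
        """Build the model from a synthetic cohort generated on the fly."""
        from .synthetic import generate_cohort, default_state_process
        from .networks import default_assignment as _da
        assignment = kwargs.pop("assignment", None) or _da(
            cohort_config.n_components)
        if state_config is None:
            state_config = default_state_process(assignment)
        manifest, tcs, truth = generate_cohort(cohort_config, state_config)
        model = cls(tcs, assignment=assignment, manifest=manifest, **kwargs)
        model.truth_labels = truth
        return model

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        k: int | None = None,
        k_range=range(2, 11),
        n_init: int = 20,
        select_n_init: int = 5,
        max_iter: int = 300,
        seed: int = 0,
        louvain_restarts: int = 10,
        negative_weight_rule: str = "asym",
    ) -> "DynamicFCResults":
        prepped = {
            p: (_prep.preprocess(ts, despike_c=self.despike_c,
                                 f_lo=self.band[0], f_hi=self.band[1])
                if self.do_prep else ts)
            for p, ts in self.timecourses.items()
        }
        static = {p: _conn.static_fc(ts) for p, ts in prepped.items()}
        wfc = {
            p: _conn.sliding_window_fc(ts, w=self.window, s=self.slide,
                                       taper=self.taper)
            for p, ts in prepped.items()
        }
        pooled = np.concatenate([wfc[p].values for p in wfc], axis=0)
        selection = None
        if k is None:
            k, selection = _states.select_k(
                pooled, k_range=k_range, seed=seed, n_init=select_n_init)
        state_model = _states.cluster_windows(
            wfc, k=k, n_init=n_init, max_iter=max_iter, seed=seed)
        summary = _states.participant_state_medians(wfc, state_model.labels, k)

        metrics_rows = []
        trans_rows = []
        for p in wfc:
            lab = state_model.labels[p]
            ft = _metrics.fraction_time(lab, k)
            dw = _metrics.mean_dwell_time(lab, k)
            st = _metrics.stickiness(lab, k)
            ac = _metrics.state_average_connectivity(wfc[p], lab, k)
            for s in range(k):
                if summary.visited[p][s]:
                    q, _ = _metrics.modularity_louvain(
                        _conn.devectorize(summary.medians[p][s]),
                        seed=seed, n_restarts=louvain_restarts,
                        negative_weight_rule=negative_weight_rule)
                else:
                    q = np.nan
                metrics_rows.append({
                    "participant_id": p, "state": s + 1,
                    "fraction_time": ft[s], "mean_dwell_time": dw[s],
                    "stickiness": int(st[s]),
                    "avg_connectivity": ac[s], "modularity": q,
                    "visited": bool(summary.visited[p][s]),
                })
            ordered, unordered = _metrics.transition_counts(lab, k)
            for a in range(k):
                for b in range(a + 1, k):
                    trans_rows.append({
                        "participant_id": p, "state_a": a + 1, "state_b": b + 1,
                        "count": int(unordered[a, b]),
                        "a_to_b": int(ordered[a, b]),
                        "b_to_a": int(ordered[b, a]),
                    })

        asoc_rows = []
        for p in wfc:
            t = _metrics.asoc(wfc[p], self.assignment)
            row = {"participant_id": p, "grand": t.grand}
            row.update({f"intra_{n}": v for n, v in t.intra.items()})
            row.update({f"inter_{n}": v for n, v in t.inter.items()})
            row.update({f"pair_{a}-{b}": v for (a, b), v in t.pairwise.items()})
            asoc_rows.append(row)

        return DynamicFCResults(
            model=self,
            k=k,
            state_model=state_model,
            selection=selection,
            state_summary=summary,
            static_fc=static,
            windowed_fc=wfc,
            metrics=pd.DataFrame(metrics_rows),
            transitions=pd.DataFrame(trans_rows),
            asoc=pd.DataFrame(asoc_rows),
            seed=seed,
        )


@dataclass
class DynamicFCResults:
    """Fitted dynamic-FC state results for a cohort."""

    model: DynamicFCModel
    k: int
    state_model: _states.StateModel
    selection: pd.DataFrame | None
    state_summary: _states.StateSummary
    static_fc: dict = field(repr=False, default_factory=dict)
    windowed_fc: dict = field(repr=False, default_factory=dict)
    metrics: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)
    transitions: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)
    asoc: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)
    seed: int = 0

    @property
    def n_participants(self) -> int:
        return len(self.model.timecourses)

    @property
    def n_pairs(self) -> int:
        return self.state_model.centroids.shape[1]

    def state_occupancy(self) -> pd.Series:
        return pd.Series(self.state_model.occupancy,
                         index=[f"state {s+1}" for s in range(self.k)],
                         name="windows")

    def summary(self) -> str:
        occ = self.state_model.occupancy
        total = occ.sum()
        lines = [
            "Dynamic FC state model",
            "=" * 58,
            f"participants:          {self.n_participants}",
            f"components / pairs:    {len(self.model.assignment.component_ids)}"
            f" / {self.n_pairs}",
            f"window / slide (TR):   {self.model.window} / {self.model.slide}"
            f"   taper: {self.model.taper or 'rectangular'}",
            f"states (k):            {self.k}"
            + ("" if self.selection is None else
               f"   [elbow k={self.selection.attrs['elbow_k']},"
               f" Dunn k={self.selection.attrs['dunn_k']},"
               f" converged={self.selection.attrs['converged']}]"),
            f"within-cluster L1 cost: {self.state_model.cost:.1f}",
            "-" * 58,
            "state   occupancy  frac   mean dwell  avg conn  modularity",
        ]
        for s in range(self.k):
            sub = self.metrics[self.metrics["state"] == s + 1]
            lines.append(
                f"  {s+1:<5d} {occ[s]:>8d}  {occ[s]/total:5.3f}  "
                f"{sub['mean_dwell_time'].mean():>9.2f}  "
                f"{sub['avg_connectivity'].mean():>8.3f}  "
                f"{sub['modularity'].mean():>9.3f}")
        lines.append("=" * 58)
        return "\n".join(lines)
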