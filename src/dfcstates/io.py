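"""Plain-text readers and writers for every pipeline artifact.

Time-courses are one TSV per participant (rows = TRs, columns = component
ids); the cohort manifest, truth labels, FC vectors, state labels,
metrics, ASOC and statistics tables are tidy TSVs; configs and the run
manifest are YAML/JSON.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectivity import FCVector, WindowedFCSeries
from .networks import NetworkAssignment
from .prep import ComponentTimecourseSet


# ----- time-courses --------------------------------------------------------

def write_timecourses(ts: ComponentTimecourseSet, path) -> None:
    df = pd.DataFrame(ts.values.T, columns=list(ts.component_ids))
    df.insert(0, "TR", np.arange(ts.n_timepoints))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_timecourses(path, tr: float, participant_id: str = "") -> ComponentTimecourseSet:
    df = pd.read_csv(path, sep="\t")
    comps = [c for c in df.columns if c != "TR"]
    return ComponentTimecourseSet(
        values=df[comps].to_numpy().T, tr=tr,
        component_ids=tuple(comps),
        participant_id=participant_id or Path(path).stem,
    )


# ----- FC vectors ----------------------------------------------------------

def pair_labels(pair_ids) -> list[str]:
    return [f"{i}-{j}" for i, j in pair_ids]


def write_fc_vectors(fcs: dict, path) -> None:
    """Static FC vectors, one row per participant."""
    first = next(iter(fcs.values()))
    rows = {p: fc.values for p, fc in fcs.items()}
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=pair_labels(first.pair_ids))
    df.index.name = "participant_id"
    df.to_csv(path, sep="\t", float_format="%.8g")


def write_windowed_fc(wfc: WindowedFCSeries, path) -> None:
    df = pd.DataFrame(wfc.values, columns=pair_labels(wfc.pair_ids))
    df.insert(0, "window_start_TR", wfc.window_starts)
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_pair_legend(pair_ids, path) -> None:
    df = pd.DataFrame(pair_ids, columns=["component_i", "component_j"])
    df.insert(0, "pair", pair_labels(pair_ids))
    df.to_csv(path, sep="\t", index=False)


# ----- assignment / labels / config ---------------------------------------

def write_assignment(assignment: NetworkAssignment, path) -> None:
    df = pd.DataFrame(
        {"component_id": list(assignment.mapping),
         "network": [assignment.mapping[c] for c in assignment.mapping]})
    df.to_csv(path, sep="\t", index=False)


def read_assignment(path) -> NetworkAssignment:
    df = pd.read_csv(path, sep="\t")
    return NetworkAssignment(dict(zip(df["component_id"], df["network"])))


def write_state_labels(labels: dict, window_starts: dict, path) -> None:
    rows = []
    for p, lab in labels.items():
        starts = window_starts[p]
        for w, s in zip(starts, lab):
            rows.append((p, int(w), int(s)))
    pd.DataFrame(rows, columns=["participant_id", "window_start_TR", "state"]) \
        .to_csv(path, sep="\t", index=False)


def write_truth_labels(truth: dict, path) -> None:
    rows = [(p, t, int(s)) for p, lab in truth.items()
            for t, s in enumerate(lab)]
    pd.DataFrame(rows, columns=["participant_id", "TR", "state"]) \
        .to_csv(path, sep="\t", index=False)


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def dump_config(cfg: dict, path) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    else:
        path.write_text(json.dumps(cfg, indent=2, sort_keys=False))


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, default=_default))
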