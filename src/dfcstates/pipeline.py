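"""End-to-end orchestration from a single config.

Stages: (optional) synthesize -> prep -> static FC -> windowed FC ->
state clustering -> dynamic metrics + ASOC -> clinical scores + EDSS
split -> statistics -> report tables.  Every stage writes tidy TSV/JSON
artifacts into the output directory, and a run manifest records config
hash, seeds, window parameters, k diagnostics and family sizes so that
identical config + seeds reproduce identical outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical as _clin
from . import io as _io
from . import metrics as _metrics
from . import stats as _stats
from .model import DynamicFCModel
from .networks import default_assignment
from .synthetic import CohortConfig, default_state_process

log = logging.getLogger(__name__)

GROUP_PAIRS = (
    ("HC", "no_disability"),
    ("HC", "mild_moderate"),
    ("no_disability", "mild_moderate"),
)


def default_config() -> dict:
    """Shipped defaults; every analysis constant lives here."""
    return {
        "cohort": {
            "n_hc": 20, "n_nodis": 10, "n_mild": 10, "n_median": 4,
            "n_components": 47, "n_timepoints": 255, "tr": 2.25,
            "missingness_rate": 0.05,
        },
        "window": {"w": 22, "s": 1, "taper": None},
        "band": [0.01, 0.15],
        "despike_c": 4.0,
        "k": 5,                  # set to null to run elbow/Dunn selection
        "k_range": [2, 10],
        "kmeans": {"n_init": 10, "select_n_init": 4, "max_iter": 150},
        "alpha": 0.05,
        "n_perm": 999,
        "edss_percentiles": [30, 70],
        "seed": 0,
    }


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class ValidationReport:
    failures: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def validate_inputs(timecourses: dict, manifest: pd.DataFrame,
                    assignment) -> ValidationReport:
    """Shape/coverage/grid checks on a loaded cohort; failures are listed."""
    rep = ValidationReport()
    shapes = {p: ts.values.shape for p, ts in timecourses.items()}
    if shapes:
        from collections import Counter
        common = Counter(shapes.values()).most_common(1)[0][0]
        for p, s in shapes.items():
            if s != common:
                rep.failures.append(
                    f"shape mismatch for {p}: {s} (expected {common})")
        first = next(iter(timecourses.values()))
        if first.tr <= 0:
            rep.failures.append("TR missing or non-positive")
        missing = assignment.check_covers(list(first.component_ids))
        for c in missing:
            rep.failures.append(f"component {c} missing from assignment")
    if "participant_id" not in manifest.columns:
        rep.failures.append("manifest lacks participant_id")
    else:
        absent = set(manifest["participant_id"]) - set(timecourses)
        for p in sorted(absent):
            rep.failures.append(f"no time-courses for {p}")
    if "EDSS" in manifest.columns:
        e = pd.to_numeric(manifest["EDSS"], errors="coerce").dropna()
        bad = e[(e < 0) | (e > 10) |
                (np.abs(e * 2 - np.round(e * 2)) > 1e-9)]
        for p, v in zip(manifest.loc[bad.index, "participant_id"], bad):
            rep.failures.append(f"EDSS off-grid for {p}: {v}")
    miss = manifest.isna().mean().mean() if len(manifest) else 0.0
    log.info("input validation: %d failure(s); overall missingness %.1f%%",
             len(rep.failures), 100 * miss)
    return rep


def _metric_families(results, metrics_wide, subgroups, age, alpha):
    """KW omnibus + Dunn post-hoc per state x measure on age residuals."""
    rows = []
    for (state, measure), vals in metrics_wide.items():
        data, grp = [], []
        for g in ("HC", "no_disability", "mild_moderate"):
            v = vals.get(g)
            if v is None or len(v) < 2:
                break
            data.append(v)
            grp.append(g)
        if len(data) < 3:
            continue
        try:
            h, df, p = _stats.kruskal_wallis(*data)
        except ValueError:
            continue
        fam = f"metric:{measure}:state{state}"
        post = _stats.dunns_posthoc(dict(zip(grp, data)), family=fam)
        post["omnibus_chi2"] = h
        post["omnibus_p"] = p
        post["omnibus_rejected"] = p < alpha
        post["state"] = state
        post["measure"] = measure
        rows.append(post)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()


def run_pipeline(config: dict | str | Path, outdir, seed: int | None = None):
    """Run the full analysis; returns (results, stats_tables, manifest_path).

    ``config`` is a dict or a YAML/JSON path; ``seed`` overrides the
    config seed.  Artifacts are written under ``outdir``.
    """
    t_start = time.time()
    if not isinstance(config, dict):
        config = _io.load_config(config)
    cfg = default_config()
    for key, val in config.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    if seed is not None:
        cfg["seed"] = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_times: dict = {}
    manifest_info: dict = {
        "config_hash": _config_hash(cfg), "config": cfg, "seed": cfg["seed"],
        "window": cfg["window"],
    }

    def _stage(name):
        stage_times[name] = time.time()
        log.info("stage: %s", name)

    try:
        _stage("synthesize")
        cohort = CohortConfig(
            seed=cfg["seed"], **{k: v for k, v in cfg["cohort"].items()})
        assignment = default_assignment(cohort.n_components)
        state_cfg = default_state_process(assignment)
        model = DynamicFCModel.from_synthetic(
            cohort, state_cfg,
            assignment=assignment,
            window=cfg["window"]["w"], slide=cfg["window"]["s"],
            taper=cfg["window"]["taper"], band=tuple(cfg["band"]),
            despike_c=cfg["despike_c"],
        )
        manifest = model.manifest
        rep = validate_inputs(model.timecourses, manifest, assignment)
        if not rep.ok:
            raise RuntimeError(f"input validation failed: {rep.failures}")
        manifest.to_csv(outdir / "cohort_manifest.tsv", sep="\t", index=False)
        _io.write_assignment(assignment, outdir / "network_assignment.tsv")
        _io.write_truth_labels(model.truth_labels, outdir / "truth_labels.tsv")

        _stage("fit")
        if cfg["window"]["w"] > cohort.n_timepoints:
            raise RuntimeError("stage windowed-FC: window exceeds scan length")
        k = cfg["k"]
        res = model.fit(
            k=k,
            k_range=range(cfg["k_range"][0], cfg["k_range"][1] + 1),
            n_init=cfg["kmeans"]["n_init"],
            select_n_init=cfg["kmeans"]["select_n_init"],
            max_iter=cfg["kmeans"]["max_iter"],
            seed=cfg["seed"],
        )
        manifest_info["k"] = res.k
        if res.selection is not None:
            res.selection.to_csv(outdir / "k_selection.tsv", sep="\t",
                                 index=False)
            manifest_info["k_selection"] = dict(res.selection.attrs)
        np.savetxt(outdir / "state_centroids.tsv",
                   res.state_model.centroids, delimiter="\t", fmt="%.8g")
        _io.write_fc_vectors(res.static_fc, outdir / "static_fc.tsv")
        _io.write_pair_legend(
            next(iter(res.static_fc.values())).pair_ids,
            outdir / "pair_legend.tsv")
        _io.write_state_labels(
            res.state_model.labels,
            {p: res.windowed_fc[p].window_starts for p in res.windowed_fc},
            outdir / "state_labels.tsv")
        res.metrics.to_csv(outdir / "dynamic_metrics.tsv", sep="\t",
                           index=False, float_format="%.8g")
        res.transitions.to_csv(outdir / "transitions.tsv", sep="\t",
                               index=False)
        res.asoc.to_csv(outdir / "asoc.tsv", sep="\t", index=False,
                        float_format="%.8g")

        _stage("clinical")
        patients = manifest[manifest["group"] == "MS"].set_index(
            "participant_id")
        domains = _clin.domain_composite(patients)
        grouping = _clin.edss_split(
            patients["EDSS"], *cfg["edss_percentiles"])
        domains["subgroup"] = grouping.subgroup
        domains.to_csv(outdir / "clinical_domains.tsv", sep="\t",
                       float_format="%.8g")
        subgroup = manifest.set_index("participant_id")["group"].copy()
        pat_sub = grouping.subgroup
        subgroup.loc[pat_sub.index] = pat_sub
        age = manifest.set_index("participant_id")["age"]

        _stage("stats")
        alpha = cfg["alpha"]
        n_perm = cfg["n_perm"]
        tables = run_statistics(res, domains, subgroup, age,
                                n_perm=n_perm, alpha=alpha, seed=cfg["seed"])
        for name, tab in tables.items():
            tab.to_csv(outdir / f"stats_{name}.tsv", sep="\t", index=False,
                       float_format="%.8g")

        _stage("report")
        report = build_report(res, tables, domains, alpha)
        (outdir / "report.txt").write_text(report)
        manifest_info["family_sizes"] = {
            name: tab.groupby("family").size().to_dict()
            for name, tab in tables.items() if "family" in tab.columns
        }
    except Exception as exc:
        failed = list(stage_times)[-1] if stage_times else "init"
        _io.write_json({"failed_stage": failed, "error": str(exc),
                        **manifest_info}, outdir / "run_manifest.json")
        raise
    manifest_info["stage_seconds"] = {
        s: round(time.time() - t, 3) for s, t in stage_times.items()}
    manifest_info["manifest_hash"] = _config_hash(
        {k: v for k, v in manifest_info.items() if k != "stage_seconds"})
    _io.write_json(manifest_info, outdir / "run_manifest.json")
    log.info("pipeline finished in %.1f s", time.time() - t_start)
    return res, tables, outdir / "run_manifest.json"


def run_statistics(res, domains: pd.DataFrame, subgroup: pd.Series,
                   age: pd.Series, n_perm: int = 999, alpha: float = 0.05,
                   seed: int = 0) -> dict:
    """The full statistical battery on fitted results.

    Returns a dict of tidy tables: ``static_fc``, ``dynamic_fc`` (mass
    permutation T per group pair [x state], family-wise FDR), ``metrics``
    and ``asoc`` (age-residual KW + Dunn), ``domain_groups`` (permutation
    tests on the 7 domain scores), and ``correlations`` (age-controlled
    Spearman partials per state x domain, FDR within state x domain).
    """
    pids = list(res.static_fc)
    sub = subgroup.reindex(pids)
    groups = {g: [p for p in pids if sub[p] == g]
              for g in ("HC", "no_disability", "mild_moderate")}
    k = res.k
    n_pairs = res.n_pairs
    pair_names = _io.pair_labels(next(iter(res.static_fc.values())).pair_ids)

    # ---- mass permutation T on static FC, family = group pair
    static_rows = []
    X_static = {p: res.static_fc[p].values for p in pids}
    for gi, (g1, g2) in enumerate(GROUP_PAIRS):
        p1, p2 = groups[g1], groups[g2]
        if len(p1) < 2 or len(p2) < 2:
            continue
        A = np.array([X_static[p] for p in p1])
        B = np.array([X_static[p] for p in p2])
        t, pv = _stats.mass_permutation_t(A, B, n_perm=n_perm,
                                          seed=seed + gi)
        fam = f"static:{g1}_vs_{g2}"
        for j in range(n_pairs):
            static_rows.append((f"{fam}:{pair_names[j]}", fam, g1, g2,
                                t[j], pv[j], len(p1), len(p2)))
    static_tab = pd.DataFrame(
        static_rows, columns=["test_id", "family", "group1", "group2",
                              "statistic", "p", "n1", "n2"])
    if len(static_tab):
        static_tab = _stats.apply_family_correction(static_tab)

    # ---- mass permutation T on per-state median FC, family = pair x state
    dyn_rows = []
    med = res.state_summary.medians
    for s in range(k):
        for gi, (g1, g2) in enumerate(GROUP_PAIRS):
            p1 = [p for p in groups[g1] if res.state_summary.visited[p][s]]
            p2 = [p for p in groups[g2] if res.state_summary.visited[p][s]]
            if len(p1) < 2 or len(p2) < 2:
                continue
            A = np.array([med[p][s] for p in p1])
            B = np.array([med[p][s] for p in p2])
            t, pv = _stats.mass_permutation_t(
                A, B, n_perm=n_perm, seed=seed + 100 + 10 * s + gi)
            fam = f"dfc:state{s+1}:{g1}_vs_{g2}"
            for j in range(n_pairs):
                dyn_rows.append((f"{fam}:{pair_names[j]}", fam, g1, g2,
                                 s + 1, t[j], pv[j], len(p1), len(p2)))
    dyn_tab = pd.DataFrame(
        dyn_rows, columns=["test_id", "family", "group1", "group2", "state",
                           "statistic", "p", "n1", "n2"])
    if len(dyn_tab):
        dyn_tab = _stats.apply_family_correction(dyn_tab)

    # ---- temporal metrics + ASOC: age residuals -> KW -> Dunn
    age_v = age.reindex(pids)

    def _group_residual_values(series: pd.Series):
        """Residualize on age over all participants with data, split by group."""
        s = series.reindex(pids)
        ok = s.notna() & age_v.notna()
        if ok.sum() < 3:
            return {}
        resid = pd.Series(
            _stats.age_residuals(s[ok].to_numpy(), age_v[ok].to_numpy()),
            index=s.index[ok])
        return {g: resid.reindex(groups[g]).dropna().to_numpy()
                for g in groups}

    metrics_wide = {}
    for measure in ("fraction_time", "mean_dwell_time", "stickiness",
                    "avg_connectivity", "modularity"):
        for s in range(k):
            m = res.metrics[res.metrics["state"] == s + 1].set_index(
                "participant_id")[measure].astype(float)
            if measure in ("fraction_time", "stickiness"):
                vals = m  # defined (possibly 0) for every participant
            else:
                vals = m.dropna()
            metrics_wide[(s + 1, measure)] = _group_residual_values(vals)
    # unordered transition counts per state pair
    for (a, b), sub_t in res.transitions.groupby(["state_a", "state_b"]):
        series = sub_t.set_index("participant_id")["count"].astype(float)
        metrics_wide[(f"{a}-{b}", "transitions")] = _group_residual_values(
            series)
    metric_tab = _metric_families(None, metrics_wide, subgroup, age, alpha)

    asoc_wide = {}
    asoc_idx = res.asoc.set_index("participant_id")
    for col in asoc_idx.columns:
        asoc_wide[(col, "asoc")] = _group_residual_values(
            asoc_idx[col].astype(float))
    asoc_tab = _metric_families(None, asoc_wide, subgroup, age, alpha)

    # ---- domain clinical scores: permutation T between patient subgroups
    dom_rows = []
    for di, domain in enumerate(_clin.DOMAINS):
        if domain not in domains.columns:
            continue
        a = domains.loc[domains["subgroup"] == "no_disability", domain].dropna()
        b = domains.loc[domains["subgroup"] == "mild_moderate", domain].dropna()
        if len(a) < 2 or len(b) < 2:
            continue
        t, pv = _stats.permutation_t_test(a.to_numpy(), b.to_numpy(),
                                          n_perm=n_perm, seed=seed + 200 + di)
        dom_rows.append({
            "test_id": f"domain:{domain}", "family": "domains",
            "domain": domain, "statistic": t, "p": pv,
            "d": _stats.cohens_d(a.to_numpy(), b.to_numpy()),
            "n1": len(a), "n2": len(b),
        })
    dom_tab = pd.DataFrame(dom_rows)
    if len(dom_tab):
        dom_tab = _stats.apply_family_correction(dom_tab)

    # ---- age-controlled Spearman partials: state x domain, FDR per family
    corr_rows = []
    pat = [p for p in pids if sub[p] in ("no_disability", "mild_moderate",
                                         "excluded_median", "unassigned")]
    pat = [p for p in pat if p in domains.index]
    age_pat = age.reindex(pat).to_numpy()
    for s in range(k):
        Xs = np.array([med[p][s] for p in pat])  # may contain NaN rows
        for domain in _clin.DOMAINS:
            if domain not in domains.columns:
                continue
            y = domains.reindex(pat)[domain].to_numpy()
            fam = f"corr:state{s+1}:{domain}"
            try:
                rho, pv, n = _stats.mass_spearman_partial(Xs, y, age_pat)
            except ValueError:
                rho = np.zeros(n_pairs)
                pv = np.ones(n_pairs)
                n = 0
            for j in range(n_pairs):
                corr_rows.append((f"{fam}:{pair_names[j]}", fam, s + 1,
                                  domain, rho[j], pv[j], n))
    corr_tab = pd.DataFrame(
        corr_rows, columns=["test_id", "family", "state", "domain",
                            "statistic", "p", "n"])
    if len(corr_tab):
        corr_tab = _stats.apply_family_correction(corr_tab)

    return {
        "static_fc": static_tab, "dynamic_fc": dyn_tab,
        "metrics": metric_tab, "asoc": asoc_tab,
        "domain_groups": dom_tab, "correlations": corr_tab,
    }


def build_report(res, tables: dict, domains: pd.DataFrame,
                 alpha: float = 0.05) -> str:
    """Plain-text report mirroring the study's table layout."""
    lines = [res.summary(), ""]
    lines.append("Clinical domain scores (impairment-coded z)")
    lines.append("-" * 58)
    dom_cols = [c for c in _clin.DOMAINS if c in domains.columns]
    desc = domains.groupby("subgroup")[dom_cols].mean().round(3)
    lines.append(desc.to_string())
    lines.append("")
    for name, tab in tables.items():
        if not len(tab):
            continue
        sig = tab[tab["p_fdr"] < alpha] if "p_fdr" in tab.columns else tab
        lines.append(f"{name}: {len(tab)} tests, "
                     f"{len(sig)} significant at FDR alpha={alpha}")
        if len(sig) and len(sig) <= 40:
            cols = [c for c in ("test_id", "statistic", "p", "p_fdr", "d")
                    if c in sig.columns]
            lines.append(sig[cols].round(4).to_string(index=False))
        lines.append("")
    return "\n".join(lines)
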