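"""Multi-domain clinical impairment scores and the EDSS subgroup split.

Raw neuropsychological, clinical and structural test scores are
standardized within the patient cohort (z-score over non-missing
patients), averaged into seven domain composites (vision, motor, fatigue,
depression, cognition, brain volume, lesion load), and impairment-coded:
vision, cognition and brain volume are multiplied by -1 so that higher
always means worse.  Patients are split into "no disability" and
"mild-to-moderate disability" subgroups at the lower/upper 30th
percentiles of EDSS, with patients tied exactly at the sample median
excluded.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import CLINICAL_TESTS, RECODE_DOMAINS

DOMAINS = ("vision", "motor", "fatigue", "depression", "cognition",
           "brain_volume", "lesion_load")

#: default test -> domain map (the shipped clinical battery layout)
DEFAULT_DOMAIN_MAP: dict = {test: domain for test, domain in CLINICAL_TESTS}


def test_zscore(raw: pd.Series) -> pd.Series:
    """Z-score a test over non-missing patients ((x - mean)/SD, n-1 SD).

    Missing values stay missing and are excluded from the mean and SD.
    """
    x = pd.to_numeric(raw, errors="coerce")
    ok = x.dropna()
    if len(ok) < 2 or ok.std(ddof=1) == 0:
        raise ValueError(f"test {raw.name!r} has fewer than 2 values or zero spread")
    return (x - ok.mean()) / ok.std(ddof=1)


def domain_composite(
    raw: pd.DataFrame,
    domain_map: dict | None = None,
    recode: tuple = RECODE_DOMAINS,
) -> pd.DataFrame:
    """Impairment-coded domain composite z-scores per patient.

    Each test column is z-scored across patients, composites are the mean
    of the *available* test z-scores per domain (available-case deletion;
    single-test domains pass through), and then the ``recode`` domains are
    multiplied by -1 so every composite is an impairment index.  A patient
    missing every test of a domain gets a missing composite.
    """
    if domain_map is None:
        domain_map = DEFAULT_DOMAIN_MAP
    unknown = [t for t in domain_map if t not in raw.columns]
    if unknown:
        raise ValueError(f"tests in domain map missing from data: {unknown}")
    z = pd.DataFrame({t: test_zscore(raw[t]) for t in domain_map}, index=raw.index)
    out = pd.DataFrame(index=raw.index)
    for domain in DOMAINS:
        tests = [t for t, d in domain_map.items() if d == domain]
        if not tests:
            continue
        comp = z[tests].mean(axis=1, skipna=True)  # NaN iff all tests missing
        if domain in recode:
            comp = -comp
        out[domain] = comp
    return out


@dataclass
class EDSSGrouping:
    """Result of the percentile-based EDSS split."""

    table: pd.DataFrame = field(repr=False)  # columns: EDSS, subgroup
    median: float = np.nan
    lower_cut: float = np.nan
    upper_cut: float = np.nan

    @property
    def subgroup(self) -> pd.Series:
        return self.table["subgroup"]


def _nearest_rank(values: np.ndarray, pct: float) -> float:
    """Nearest-rank quantile: the ceil(pct/100 * n)-th smallest value."""
    v = np.sort(values)
    rank = int(np.ceil(pct / 100.0 * v.size))
    return float(v[max(rank, 1) - 1])


def edss_split(
    edss: pd.Series, lower_pct: float = 30.0, upper_pct: float = 70.0
) -> EDSSGrouping:
    """Split patients by EDSS at the lower/upper percentile thresholds.

    Patients whose score equals the sample median exactly are excluded
    (``excluded_median``); of the rest, EDSS <= the nearest-rank
    ``lower_pct`` quantile gives ``no_disability`` and EDSS >= the
    ``upper_pct`` quantile ``mild_moderate``.  Patients between the cuts
    are ``unassigned``; missing ratings are ``unrated``.  EDSS values are
    validated to the 0-10 scale in 0.5 steps.
    """
    x = pd.to_numeric(edss, errors="coerce")
    rated = x.dropna()
    offgrid = rated[(rated < 0) | (rated > 10) |
                    (np.abs(rated * 2 - np.round(rated * 2)) > 1e-9)]
    if len(offgrid):
        raise ValueError(f"EDSS values off the 0-10/0.5 grid: {sorted(set(offgrid))}")
    if len(rated) < 5:
        raise ValueError("need at least 5 rated patients")
    if rated.nunique() == 1:
        raise ValueError("all EDSS scores identical; split undefined")
    med = float(np.median(rated))
    lo = _nearest_rank(rated.to_numpy(), lower_pct)
    hi = _nearest_rank(rated.to_numpy(), upper_pct)
    sub = pd.Series("unassigned", index=x.index, dtype=object)
    sub[x.isna()] = "unrated"
    tied = x == med
    sub[tied] = "excluded_median"
    sub[(x <= lo) & ~tied & x.notna()] = "no_disability"
    sub[(x >= hi) & ~tied & x.notna()] = "mild_moderate"
    table = pd.DataFrame({"EDSS": x, "subgroup": sub})
    return EDSSGrouping(table=table, median=med, lower_cut=lo, upper_cut=hi)
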