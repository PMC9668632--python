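import numpy as np
import pandas as pd
import pytest

from dfcstates import (
    CohortConfig, StateProcessConfig, cohens_d, default_state_process,
    fraction_time, generate_clinical_cohort, generate_cohort,
    generate_state_sequence, generate_timecourses, repair_correlation,
    stationary_distribution, transition_matrix_from_stay, window_truth_labels,
)
from dfcstates.clinical import domain_composite
from dfcstates.synthetic import shifted_state_process


def _cfg(P, n_comp=3, seed=0):
    k = P.shape[0]
    return StateProcessConfig(k, P, [np.eye(n_comp)] * k, seed=seed)


class TestStateSequence:
    def test_absorbing_identity_matrix(self):
        cfg = _cfg(np.eye(4))
        seq = generate_state_sequence(cfg, 10, seed=0, start_state=1)
        assert list(seq) == [1] * 10

    def test_uniform_chain_long_run_fraction(self):
        cfg = _cfg(np.full((2, 2), 0.5))
        seq = generate_state_sequence(cfg, 10_000, seed=1)
        assert fraction_time(seq, 2)[0] == pytest.approx(0.5, abs=0.02)

    def test_deterministic_cycle(self):
        P = np.array([[0, 1, 0], [0, 0, 1], [1.0, 0, 0]])
        cfg = _cfg(P)
        seq = generate_state_sequence(cfg, 6, seed=0, start_state=1)
        assert list(seq) == [1, 2, 3, 1, 2, 3]

    def test_seed_reproducibility(self, state_process):
        a = generate_state_sequence(state_process, 200, seed=7)
        b = generate_state_sequence(state_process, 200, seed=7)
        assert np.array_equal(a, b)

    def test_non_stochastic_rows_rejected(self):
        with pytest.raises(ValueError, match="stochastic"):
            _cfg(np.array([[0.5, 0.4], [0.5, 0.5]]))

    def test_long_run_matches_stationary(self, state_process):
        # sticky chain: effective sample is ~n/(2*dwell), so use a long run
        seq = generate_state_sequence(state_process, 200_000, seed=3)
        pi = stationary_distribution(state_process.transition_matrix)
        assert np.abs(fraction_time(seq, 5) - pi).max() < 0.02

    def test_stationary_occupancy_decreasing(self, state_process):
        pi = stationary_distribution(state_process.transition_matrix)
        assert np.all(np.diff(pi) < 0)  # state 1 most frequent ... state 5 least


class TestRepairCorrelation:
    def test_psd_matrix_untouched(self):
        C = np.array([[1, 0.5], [0.5, 1.0]])
        assert np.allclose(repair_correlation(C), C)

    def test_indefinite_matrix_repaired(self):
        C = np.array([[1, 0.9, -0.9], [0.9, 1, 0.9], [-0.9, 0.9, 1.0]])
        R = repair_correlation(C)
        assert np.linalg.eigvalsh(R).min() >= -1e-10
        assert np.allclose(np.diag(R), 1.0)
        assert np.allclose(R, R.T)

    def test_default_centroids_valid(self, state_process):
        for C in state_process.centroid_correlations:
            assert np.linalg.eigvalsh(C).min() >= -1e-10
            assert np.allclose(np.diag(C), 1.0)


class TestTimecourses:
    def test_identity_correlation_near_zero_pairs(self):
        cfg = _cfg(np.eye(1), n_comp=5)
        cohort = CohortConfig(n_hc=1, n_mild=1, n_nodis=1, n_median=0,
                              n_components=5, n_timepoints=20_000)
        ts, _ = generate_timecourses(cfg, cohort, participant_seed=11)
        r = np.corrcoef(ts.values)
        off = ~np.eye(5, dtype=bool)
        assert np.abs(r[off]).max() < 4 / np.sqrt(20_000) * np.sqrt(5)

    def test_planted_pair_correlation_recovered(self):
        C = np.eye(5)
        C[1, 3] = C[3, 1] = 0.6
        cfg = StateProcessConfig(1, np.eye(1), [C])
        cohort = CohortConfig(n_hc=1, n_mild=1, n_nodis=1, n_median=0,
                              n_components=5, n_timepoints=20_000)
        ts, _ = generate_timecourses(cfg, cohort, participant_seed=5)
        r = np.corrcoef(ts.values)[1, 3]
        assert r == pytest.approx(0.6, abs=0.03)

    def test_same_seed_bit_identical(self, state_process):
        cohort = CohortConfig(n_hc=1, n_mild=1, n_nodis=1, n_median=0)
        a, la = generate_timecourses(state_process, cohort, 77)
        b, lb = generate_timecourses(state_process, cohort, 77)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(la, lb)

    def test_segment_sample_correlation_matches_centroid(self, state_process):
        # within one long state segment the sample correlation converges to
        # the planted centroid
        cohort = CohortConfig(n_hc=1, n_mild=1, n_nodis=1, n_median=0,
                              n_timepoints=2000)
        ts, labels = generate_timecourses(state_process, cohort, 13)
        s = np.bincount(labels).argmax()
        idx = labels == s
        if idx.sum() >= 300:
            r = np.corrcoef(ts.values[:, idx])
            target = state_process.centroid_correlations[s - 1]
            tol = 4 / np.sqrt(idx.sum())
            off = ~np.eye(r.shape[0], dtype=bool)
            # tolerance per element, allow heavy-tail slack across 1081 pairs
            assert np.abs(r[off] - target[off]).max() < tol * 3


class TestClinicalCohort:
    def test_null_effects_no_group_difference(self):
        cohort = CohortConfig(n_hc=2, n_mild=150, n_nodis=150, n_median=0,
                              clinical_effect_sizes={}, missingness_rate=0.0,
                              seed=4)
        df = generate_clinical_cohort(cohort)
        pat = df[df["group"] == "MS"].set_index("participant_id")
        dom = domain_composite(pat)
        for d in dom.columns:
            a = dom.loc[pat["subgroup"] == "no_disability", d].dropna()
            b = dom.loc[pat["subgroup"] == "mild_moderate", d].dropna()
            assert abs(a.mean() - b.mean()) < 3 / np.sqrt(150)

    def test_planted_fatigue_effect_recovered(self):
        cohort = CohortConfig(n_hc=2, n_mild=200, n_nodis=200, n_median=0,
                              clinical_effect_sizes={"fatigue": 1.0},
                              missingness_rate=0.0, seed=9)
        df = generate_clinical_cohort(cohort)
        pat = df[df["group"] == "MS"].set_index("participant_id")
        dom = domain_composite(pat)
        a = dom.loc[pat["subgroup"] == "no_disability", "fatigue"]
        b = dom.loc[pat["subgroup"] == "mild_moderate", "fatigue"]
        d = cohens_d(b.to_numpy(), a.to_numpy())  # impairment higher in mild
        assert d == pytest.approx(1.0, abs=0.25)

    def test_zero_missingness(self):
        cohort = CohortConfig(n_hc=2, n_mild=20, n_nodis=20, n_median=0,
                              missingness_rate=0.0, seed=1)
        df = generate_clinical_cohort(cohort)
        tests = [c for c in df.columns if c not in
                 ("participant_id", "group", "subgroup", "age", "sex", "EDSS")]
        assert not df.loc[df["group"] == "MS", tests].isna().any().any()

    def test_age_older_in_disability_group(self):
        cohort = CohortConfig(n_hc=50, n_mild=200, n_nodis=200, seed=2)
        df = generate_clinical_cohort(cohort)
        mild = df.loc[df["subgroup"] == "mild_moderate", "age"]
        nodis = df.loc[df["subgroup"] == "no_disability", "age"]
        assert mild.mean() > nodis.mean() + 3

    def test_edss_structure(self):
        cohort = CohortConfig(n_hc=3, n_mild=30, n_nodis=30, n_median=17,
                              seed=6)
        df = generate_clinical_cohort(cohort)
        assert df.loc[df["subgroup"] == "no_disability", "EDSS"].max() <= 1
        assert df.loc[df["subgroup"] == "mild_moderate", "EDSS"].min() >= 2
        assert (df.loc[df["subgroup"] == "median_tied", "EDSS"] == 1.5).all()
        assert df.loc[df["group"] == "HC", "EDSS"].isna().all()


class TestFullCohort:
    def test_fixed_seed_byte_identical(self):
        cohort = CohortConfig(n_hc=2, n_mild=2, n_nodis=2, n_median=0, seed=8)
        m1, t1, l1 = generate_cohort(cohort)
        m2, t2, l2 = generate_cohort(cohort)
        pd.testing.assert_frame_equal(m1, m2)
        for p in t1:
            assert np.array_equal(t1[p].values, t2[p].values)
            assert np.array_equal(l1[p], l2[p])

    def test_occupancy_shift_raises_state5_fraction(self, state_process):
        shifted = shifted_state_process(state_process, 0.035)
        base_pi = stationary_distribution(state_process.transition_matrix)
        shift_pi = stationary_distribution(shifted.transition_matrix)
        assert shift_pi[-1] > base_pi[-1] + 0.05

    def test_window_truth_majority_vote(self):
        labels = np.array([1] * 30 + [2] * 30)
        wl = window_truth_labels(labels, w=22, s=1)
        assert wl[0] == 1 and wl[-1] == 2
        # majority flips where state 2 covers > half the window
        flip = np.flatnonzero(np.diff(wl))[0] + 1
        assert abs(flip - (30 - 11)) <= 1
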