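import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dfcstates import (
    age_residuals, apply_family_correction, bh_fdr, cohens_d, dunns_posthoc,
    kruskal_wallis, mass_permutation_t, mass_spearman_partial,
    permutation_t_test, spearman_partial,
)


# ---- independent brute-force rank oracle for KW / Dunn --------------------

def _brute_ranks(pooled):
    """Average ranks computed by explicit sorting, independent of scipy."""
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def _brute_kw(groups):
    pooled = [v for g in groups for v in g]
    ranks = _brute_ranks(pooled)
    N = len(pooled)
    off, H = 0, 0.0
    for g in groups:
        r = ranks[off:off + len(g)]
        H += (sum(r)) ** 2 / len(g)
        off += len(g)
    H = 12.0 / (N * (N + 1)) * H - 3 * (N + 1)
    # tie correction
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    tie = sum(c**3 - c for c in counts.values())
    denom = 1.0 - tie / (N**3 - N)
    return H / denom if denom > 0 else np.nan


def _brute_dunn_z(groups, a, b):
    pooled = [v for g in groups.values() for v in g]
    ranks = _brute_ranks(pooled)
    N = len(pooled)
    mean_rank, off = {}, 0
    for g, vals in groups.items():
        mean_rank[g] = sum(ranks[off:off + len(vals)]) / len(vals)
        off += len(vals)
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    tie = sum(c**3 - c for c in counts.values()) / (12.0 * (N - 1))
    se = np.sqrt((N * (N + 1) / 12.0 - tie)
                 * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
    return (mean_rank[a] - mean_rank[b]) / se


class TestPermutationT:
    def test_identical_samples(self):
        x = np.array([1.0, 2, 3, 4])
        t, p = permutation_t_test(x, x.copy(), n_perm=199, seed=0)
        assert t == 0.0
        assert p == 1.0

    def test_huge_shift_add_one_p(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30) + 10.0
        t, p = permutation_t_test(x, y, n_perm=999, seed=1)
        assert p == pytest.approx(1.0 / 1000.0)

    def test_zero_variance_both_groups(self):
        t, p = permutation_t_test(np.ones(5), np.ones(4), n_perm=199)
        assert (t, p) == (0.0, 1.0)

    def test_deterministic_under_seed(self, rng):
        x, y = rng.standard_normal(10), rng.standard_normal(12)
        assert permutation_t_test(x, y, 499, seed=5) == \
            permutation_t_test(x, y, 499, seed=5)

    def test_null_p_super_uniform(self, rng):
        """Under H0 the rejection rate at each alpha stays at/below nominal."""
        n_sim = 400
        ps = np.empty(n_sim)
        for i in range(n_sim):
            x = rng.standard_normal(12)
            y = rng.standard_normal(12)
            _, ps[i] = permutation_t_test(x, y, n_perm=199, seed=i)
        for alpha in (0.01, 0.05, 0.10):
            assert (ps <= alpha).mean() <= alpha + 2.5 * np.sqrt(
                alpha * (1 - alpha) / n_sim)

    def test_mass_matches_scalar(self, rng):
        X = rng.standard_normal((8, 5))
        Y = rng.standard_normal((9, 5)) + 0.5
        t_mass, p_mass = mass_permutation_t(X, Y, n_perm=299, seed=3)
        for j in range(5):
            t, p = permutation_t_test(X[:, j], Y[:, j], n_perm=299, seed=3)
            assert t == pytest.approx(t_mass[j])
        # observed statistic equals scipy's Welch T
        t_sp = sps.ttest_ind(X, Y, equal_var=False).statistic
        assert np.allclose(t_mass, t_sp)


class TestCohensD:
    def test_equal_means_zero(self, rng):
        x = rng.standard_normal(20)
        assert cohens_d(x, x[::-1]) == pytest.approx(0.0)

    def test_hand_oracle(self):
        # pooled variance ((1*2)+(1*2))/2 = 2 -> d = (1-3)/sqrt(2)
        d = cohens_d(np.array([0.0, 2.0]), np.array([2.0, 4.0]))
        assert d == pytest.approx(-2.0 / np.sqrt(2.0))

    def test_antisymmetry(self, rng):
        x, y = rng.standard_normal(15), rng.standard_normal(10) + 1
        assert cohens_d(x, y) == pytest.approx(-cohens_d(y, x))

    def test_zero_pooled_sd_errors(self):
        with pytest.raises(ValueError):
            cohens_d(np.ones(3), np.ones(4))


class TestBH:
    def test_hand_step_up(self):
        adj = bh_fdr([0.001, 0.01, 0.02, 0.9])
        assert np.allclose(adj, [0.004, 0.02, 4 * 0.02 / 3, 0.9])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_all_equal(self):
        assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_monotone_and_order_preserving(self, rng):
        p = rng.uniform(1e-6, 1, 30)
        adj = bh_fdr(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 0.0])

    def test_null_family_fdr_controlled(self, rng):
        m, alpha, reps = 40, 0.05, 300
        false_disc = 0
        for _ in range(reps):
            p = rng.uniform(0, 1, m)
            p = np.clip(p, 1e-12, 1)
            false_disc += (bh_fdr(p) <= alpha).sum()
        assert false_disc / reps <= alpha * m


class TestFamilyCorrection:
    def test_families_independent(self, rng):
        pa = np.clip(rng.uniform(0, 1, 10), 1e-9, 1)
        pb = np.clip(rng.uniform(0, 1, 4), 1e-9, 1)
        df = pd.DataFrame({
            "family": ["A"] * 10 + ["B"] * 4,
            "p": np.concatenate([pa, pb]),
        })
        out = apply_family_correction(df)
        assert np.allclose(out.loc[out["family"] == "A", "p_fdr"], bh_fdr(pa))
        assert np.allclose(out.loc[out["family"] == "B", "p_fdr"], bh_fdr(pb))
        # sentinel: a tiny p in B must not affect A's corrections
        df2 = df.copy()
        df2.loc[df2["family"] == "B", "p"] = 1e-9
        out2 = apply_family_correction(df2)
        assert np.allclose(out2.loc[out2["family"] == "A", "p_fdr"],
                           out.loc[out["family"] == "A", "p_fdr"])

    def test_orphan_errors(self):
        df = pd.DataFrame({"family": ["A", None], "p": [0.1, 0.2]})
        with pytest.raises(ValueError, match="orphan"):
            apply_family_correction(df)


class TestAgeResiduals:
    def test_pure_age_signal_zeroed(self, rng):
        age = rng.uniform(20, 60, 40)
        resid = age_residuals(2 * age + 5, age)
        assert np.allclose(resid, 0, atol=1e-8)

    def test_independent_values_centered(self, rng):
        age = rng.uniform(20, 60, 200)
        v = rng.standard_normal(200)
        resid = age_residuals(v, age)
        assert abs(np.corrcoef(resid, age)[0, 1]) < 1e-8
        assert abs(resid.mean()) < 1e-10

    def test_constant_age_errors(self):
        with pytest.raises(ValueError):
            age_residuals(np.arange(5.0), np.full(5, 30.0))


class TestKruskalDunn:
    def test_identical_groups(self):
        g = list(range(1, 11))
        h, df, p = kruskal_wallis(g, g, g)
        assert h == pytest.approx(0.0, abs=1e-12)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_textbook_no_ties(self):
        h, df, p = kruskal_wallis([1, 2, 3], [4, 5, 6], [7, 8, 9])
        assert h == pytest.approx(_brute_kw([[1, 2, 3], [4, 5, 6], [7, 8, 9]]))

    def test_rank_invariance_monotone_transform(self, rng):
        g1, g2, g3 = (rng.uniform(0, 3, 8) for _ in range(3))
        h1, *_ = kruskal_wallis(g1, g2, g3)
        h2, *_ = kruskal_wallis(np.exp(g1), np.exp(g2), np.exp(g3))
        assert h1 == pytest.approx(h2)

    def test_exhaustive_small_integer_datasets(self):
        """KW and Dunn agree with the brute-force rank oracle, n <= 9."""
        rng = np.random.default_rng(0)
        for _ in range(60):
            sizes = rng.integers(2, 4, size=3)
            data = [list(rng.integers(0, 4, s)) for s in sizes]
            if len({v for g in data for v in g}) == 1:
                continue
            h, df, p = kruskal_wallis(*data)
            assert h == pytest.approx(_brute_kw(data), abs=1e-10)
            groups = {f"g{i}": np.array(g, float) for i, g in enumerate(data)}
            post = dunns_posthoc(groups)
            for _, row in post.iterrows():
                z_ref = _brute_dunn_z(groups, row["group1"], row["group2"])
                assert row["statistic"] == pytest.approx(z_ref, abs=1e-10)

    def test_dunn_sign_convention(self, rng):
        a = rng.standard_normal(10)
        b = rng.standard_normal(10) + 2
        z_ab = dunns_posthoc({"a": a, "b": b}).iloc[0]["statistic"]
        z_ba = dunns_posthoc({"b": b, "a": a}).iloc[0]["statistic"]
        assert z_ab == pytest.approx(-z_ba)

    def test_planted_shift_detected(self, rng):
        a = rng.standard_normal(30)
        b = rng.standard_normal(30)
        c = rng.standard_normal(30) + 3.0
        h, df, p = kruskal_wallis(a, b, c)
        assert p < 0.05
        post = dunns_posthoc({"a": a, "b": b, "c": c})
        sig = post[post["p_fdr"] < 0.05]
        assert set(sig["test_id"]) == {"a_vs_c", "b_vs_c"}


class TestSpearmanPartial:
    def test_perfect_monotone(self, rng):
        x = rng.standard_normal(30)
        c = rng.standard_normal(30)
        rho, p = spearman_partial(x, x.copy(), c)
        assert rho == pytest.approx(1.0)
        rho2, _ = spearman_partial(x, -x, c)
        assert rho2 == pytest.approx(-1.0)

    def test_known_partial_correlation_recovered(self, rng):
        # joint normal with target partial correlation 0.5 given z
        n = 5000
        z = rng.standard_normal(n)
        e1, e2 = rng.standard_normal(n), rng.standard_normal(n)
        x = z + e1
        y = z + 0.5 / np.sqrt(1 - 0.25) * e1 + e2
        rho_target = np.corrcoef(e1, 0.5 / np.sqrt(0.75) * e1 + e2)[0, 1]
        rho, p = spearman_partial(x, y, z)
        assert rho == pytest.approx(rho_target, abs=0.05)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        x, y, c = (rng.standard_normal(40) for _ in range(3))
        rho, p = spearman_partial(x, y, c)
        ref = pg.partial_corr(
            data=pd.DataFrame({"x": x, "y": y, "c": c}),
            x="x", y="y", covar="c", method="spearman")
        assert rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_mass_matches_scalar_with_missing(self, rng):
        X = rng.standard_normal((25, 4))
        y = rng.standard_normal(25)
        c = rng.standard_normal(25)
        y[3] = np.nan
        rho_m, p_m, n = mass_spearman_partial(X, y, c)
        assert n == 24
        for j in range(4):
            rho, p = spearman_partial(X[:, j], y, c)
            assert rho_m[j] == pytest.approx(rho, abs=1e-10)
            assert p_m[j] == pytest.approx(p, rel=1e-9)

    def test_too_few_triples_errors(self):
        with pytest.raises(ValueError):
            spearman_partial([1, 2, 3], [1, 2, 3], [1, 2, 3])
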