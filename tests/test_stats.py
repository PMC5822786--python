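"""Statistical operations against independent first-principles oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from amyshape.radial import make_directions
from amyshape.stats import (
    ClusterResult,
    build_adjacency,
    cluster_adjusted_regression,
    fdr_correct,
    find_clusters,
    mann_whitney_u,
    paired_mixed_model,
    pearson_matrix,
    vertexwise_glm,
    volume_regression,
)
from oracles import (
    bh_stepup_bruteforce,
    components_bfs,
    mwu_exact_enumeration,
    ols_normal_equations,
)


# ---------------------------------------------------------------------------
# adjacency
# ---------------------------------------------------------------------------

class TestAdjacency:
    def test_connected_symmetric_near_six_degree(self, directions_1000):
        A = build_adjacency(directions_1000)
        n_comp, _ = sparse.csgraph.connected_components(A, directed=False)
        assert n_comp == 1
        assert (A != A.T).nnz == 0
        mean_degree = A.sum() / A.shape[0]
        assert 5.5 < mean_degree < 6.0  # Euler bound: strictly below 6


# ---------------------------------------------------------------------------
# vertex-wise GLM
# ---------------------------------------------------------------------------

class TestVertexGLM:
    def test_betas_match_normal_equations_to_1e8(self):
        rng = np.random.default_rng(0)
        n, m = 40, 200
        score = rng.normal(10, 5, n)
        age = rng.normal(21, 2, n)
        etiv = rng.normal(1450, 150, n)
        Y = rng.normal(8, 1, (n, m)) + 0.05 * score[:, None]
        vs = vertexwise_glm(Y, score, age, etiv)
        X = np.column_stack([np.ones(n), score, age, etiv])
        for j in range(0, m, 17):
            beta, se, dof = ols_normal_equations(X, Y[:, j])
            assert vs.beta[j] == pytest.approx(beta[1], abs=1e-8)
            assert vs.t[j] == pytest.approx(beta[1] / se[1], abs=1e-8)

    def test_recovers_generative_coefficient(self):
        """radius = 0.08*score + 0.01*age + noise: beta lands in [0.07, 0.09]."""
        rng = np.random.default_rng(1)
        n = 200
        score = rng.normal(10, 5, n)
        age = rng.normal(21, 2, n)
        etiv = rng.normal(1450, 150, n)
        Y = (8.0 + 0.08 * score[:, None] + 0.01 * age[:, None]
             + rng.normal(0, 0.05, (n, 50)))
        vs = vertexwise_glm(Y, score, age, etiv)
        assert np.all(vs.beta > 0.07)
        assert np.all(vs.beta < 0.09)

    def test_null_type_one_error_calibrated(self):
        """Independent score vs radii at n=30: ~5% of 1000 points reach p<0.05."""
        rng = np.random.default_rng(2)
        n = 30
        Y = rng.normal(8, 0.5, (n, 1000))
        score = rng.permutation(np.repeat(np.arange(10), 3)).astype(float)
        vs = vertexwise_glm(Y, score, rng.normal(21, 2, n), rng.normal(1450, 100, n))
        frac = np.mean(vs.p < 0.05)
        assert 0.03 < frac < 0.07

    def test_constant_radii_rejected(self):
        n = 20
        rng = np.random.default_rng(3)
        Y = np.full((n, 10), 7.5)
        with pytest.raises(ValueError, match="residual variance"):
            vertexwise_glm(Y, rng.normal(size=n), rng.normal(size=n), rng.normal(size=n))

    def test_constant_score_rejected(self):
        rng = np.random.default_rng(4)
        n = 20
        Y = rng.normal(8, 1, (n, 5))
        with pytest.raises(ValueError, match="score"):
            vertexwise_glm(Y, np.full(n, 3.0), rng.normal(size=n), rng.normal(size=n))


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

class TestFDR:
    def test_all_ones_no_rejections(self):
        q, rej = fdr_correct(np.ones(100), 0.05)
        assert not rej.any()

    def test_all_zeros_all_rejected(self):
        q, rej = fdr_correct(np.zeros(50), 0.05)
        assert rej.all()
        assert np.allclose(q, 0.0)

    def test_stepup_cascade_example(self):
        _, rej = fdr_correct(np.array([0.01, 0.02, 0.03, 0.05]), 0.05)
        assert rej.all()

    def test_matches_bruteforce_on_random_vectors(self):
        """BH rejections equal the literal step-up scan, 500 random vectors."""
        rng = np.random.default_rng(5)
        for _ in range(500):
            m = int(rng.integers(5, 80))
            p = rng.random(m) ** rng.uniform(0.5, 3.0)
            alpha = float(rng.choice([0.01, 0.05, 0.1]))
            _, rej = fdr_correct(p, alpha)
            assert np.array_equal(rej, bh_stepup_bruteforce(p, alpha))

    def test_q_dominates_p_and_bonferroni_subset(self):
        rng = np.random.default_rng(6)
        p = rng.random(1000) ** 2
        q, rej = fdr_correct(p, 0.05)
        assert np.all(q >= p - 1e-15)
        bonf = p < 0.05 / len(p)
        assert np.all(rej[bonf])

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct(np.array([0.1, 1.2]), 0.05)


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------

class TestClusters:
    def test_extent_threshold_boundary(self, directions_1000):
        """Components of 14 points are eliminated; 15 points survive."""
        A = build_adjacency(directions_1000)
        adj = A.tolil().rows
        flags = np.zeros(1000, dtype=bool)

        def grow(seed, size):
            comp = [seed]
            comp_set = {seed}
            i = 0
            while len(comp_set) < size:
                for v in adj[comp[i]]:
                    if len(comp_set) < size and not flags[v] and v not in comp_set:
                        comp_set.add(v)
                        comp.append(v)
                i += 1
            return comp_set

        c14 = grow(0, 14)
        c15 = grow(999, 15)
        for c in (c14, c15):
            flags[list(c)] = True
        clusters = find_clusters(flags, A, extent_min=15)
        sizes = sorted(c.size for c in clusters)
        assert sizes == [15]
        assert set(map(int, clusters[0].indices)) == c15

    def test_no_significant_points_empty(self, directions_1000):
        A = build_adjacency(directions_1000)
        assert find_clusters(np.zeros(1000, bool), A, 15) == []

    def test_partition_matches_bfs_oracle(self, directions_1000):
        A = build_adjacency(directions_1000)
        rng = np.random.default_rng(7)
        for _ in range(20):
            flags = rng.random(1000) < rng.uniform(0.05, 0.4)
            found = {
                frozenset(map(int, c.indices))
                for c in find_clusters(flags, A, extent_min=1)
            }
            assert found == components_bfs(flags, A)


# ---------------------------------------------------------------------------
# cluster / volume regressions
# ---------------------------------------------------------------------------

class TestClusterRegression:
    def test_recovers_known_coupling(self):
        """Radii built with 0.08 mm/point on the cluster: beta within 25%."""
        rng = np.random.default_rng(8)
        n = 30
        score = rng.normal(6, 5, n).clip(0)
        age = rng.normal(21, 1.5, n)
        etiv = rng.normal(1450, 150, n)
        Y = rng.normal(7.5, 0.0, (n, 100)) + rng.normal(0, 0.1, (n, 100))
        idx = np.arange(20)
        Y[:, idx] += 0.08 * score[:, None]
        cl = cluster_adjusted_regression(
            ClusterResult(indices=idx, size=len(idx)), Y, score, age, etiv
        )
        assert cl.beta == pytest.approx(0.08, rel=0.25)
        assert cl.adjusted_mean_radii.shape == (n,)

    def test_null_betas_within_two_se(self):
        """Uncorrelated score: |beta| < 2 SE in at least 90% of simulations."""
        rng = np.random.default_rng(9)
        n = 200
        ok = 0
        for _ in range(100):
            score = rng.normal(10, 5, n)
            age = rng.normal(21, 2, n)
            etiv = rng.normal(1450, 150, n)
            Y = rng.normal(8, 0.5, (n, 30))
            cl = cluster_adjusted_regression(
                ClusterResult(indices=np.arange(30), size=30), Y, score, age, etiv
            )
            se = cl.beta / cl.t if cl.t != 0 else np.inf
            ok += abs(cl.beta) < 2 * abs(se)
        assert ok >= 90

    def test_exact_linear_relation_recovered_precisely(self):
        n = 25
        rng = np.random.default_rng(10)
        score = rng.normal(10, 5, n)
        age = rng.normal(21, 2, n)
        etiv = rng.normal(1450, 150, n)
        Y = np.tile((5.0 + 0.12 * score)[:, None], (1, 1000))
        with pytest.warns(UserWarning, match="exact linear"):
            cl = cluster_adjusted_regression(
                ClusterResult(indices=np.arange(1000), size=1000), Y, score, age, etiv
            )
        assert cl.beta == pytest.approx(0.12, abs=1e-10)
        assert cl.p == 0.0

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cluster_adjusted_regression(
                ClusterResult(indices=np.array([], dtype=int), size=0),
                np.zeros((10, 5)), np.zeros(10), np.zeros(10), np.zeros(10),
            )


class TestVolumeRegression:
    def test_exact_linear_volume(self):
        rng = np.random.default_rng(11)
        n = 20
        score = rng.normal(10, 5, n)
        age = rng.normal(21, 2, n)
        etiv = rng.normal(1450, 150, n)
        vols = 1600.0 + 12.0 * score
        with pytest.warns(UserWarning, match="exact linear"):
            beta, t, p = volume_regression(vols, score, age, etiv)
        assert beta == pytest.approx(12.0, abs=1e-9)
        assert p == 0.0

    def test_constant_volumes_rejected(self):
        n = 20
        rng = np.random.default_rng(12)
        with pytest.raises(ValueError, match="variance"):
            volume_regression(
                np.full(n, 1500.0), rng.normal(size=n), rng.normal(size=n),
                rng.normal(size=n),
            )


# ---------------------------------------------------------------------------
# correlations, rank tests, paired model
# ---------------------------------------------------------------------------

class TestPearson:
    def test_self_correlation_is_one(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 5], "b": [2.0, 1, 4, 3]})
        r, p, n = pearson_matrix(df)
        assert r.loc["a", "a"] == pytest.approx(1.0)

    def test_closed_form_example(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [2.0, 1, 4, 3]})
        r, _, _ = pearson_matrix(df)
        assert r.loc["x", "y"] == pytest.approx(0.6)

    def test_anticorrelation(self):
        x = np.array([1.0, 2, 5, 9])
        df = pd.DataFrame({"x": x, "y": -x})
        r, _, _ = pearson_matrix(df)
        assert r.loc["x", "y"] == pytest.approx(-1.0)

    def test_pairwise_deletion_reports_n(self):
        df = pd.DataFrame(
            {"x": [1.0, 2, 3, 4, 5], "y": [2.0, np.nan, 4, 3, 6]}
        )
        r, p, n = pearson_matrix(df)
        assert n.loc["x", "y"] == 4
        assert n.loc["x", "x"] == 5

    def test_zero_variance_warns_nan(self):
        df = pd.DataFrame({"x": [1.0, 1, 1, 1], "y": [2.0, 1, 4, 3]})
        with pytest.warns(UserWarning, match="zero variance"):
            r, _, _ = pearson_matrix(df)
        assert np.isnan(r.loc["x", "y"])


class TestMannWhitney:
    def test_separated_groups_exact(self):
        U, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert U == 0.0
        assert p == pytest.approx(0.1)

    def test_full_ties_midranks(self):
        U, _ = mann_whitney_u([5, 5], [5, 5])
        assert U == pytest.approx(2.0)  # n_a * n_b / 2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            a = rng.normal(0, 1, 6)
            b = rng.normal(0.5, 1, 7)
            U, p = mann_whitney_u(a, b)
            u_oracle, p_oracle = mwu_exact_enumeration(a, b)
            assert U == pytest.approx(u_oracle)
            assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(14)
        for _ in range(5):
            a = np.round(rng.normal(0, 1, 10), 6)
            b = np.round(rng.normal(0, 1, 10), 6)
            _, p_exact = mwu_exact_enumeration(a, b)
            from scipy.stats import mannwhitneyu

            p_approx = mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic").pvalue
            assert abs(p_exact - p_approx) < 0.02


class TestPairedModel:
    def test_no_change_gives_p_one(self):
        base = [5.0, 7.0, 9.0, 4.0]
        eff, t, p = paired_mixed_model(base, base)
        assert eff == 0.0
        assert p == 1.0

    def test_constant_shift_degenerate(self):
        base = np.array([5.0, 7.0, 9.0])
        with pytest.warns(UserWarning, match="zero residual"):
            eff, t, p = paired_mixed_model(base, base + 3.0)
        assert eff == pytest.approx(3.0)
        assert p == 0.0

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            paired_mixed_model([1.0], [2.0])

    def test_type_one_error_calibrated(self):
        """Null shift with subject heterogeneity: rejection rate near 0.05."""
        rng = np.random.default_rng(15)
        n_sim, n = 2000, 14
        rejections = 0
        for _ in range(n_sim):
            subject = rng.normal(0, 5, n)
            base = subject + rng.normal(0, 2, n)
            fu = subject + rng.normal(0, 2, n)
            _, _, p = paired_mixed_model(base, fu)
            rejections += p < 0.05
        assert 0.03 < rejections / n_sim < 0.07

    def test_agrees_with_mixed_model_fit(self):
        """The closed form coincides with an explicit random-intercept fit."""
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(16)
        n = 14
        subject = rng.normal(20, 6, n)
        base = subject + rng.normal(0, 2, n)
        fu = subject + 1.5 + rng.normal(0, 2, n)
        eff, t, p = paired_mixed_model(base, fu)
        df = pd.DataFrame(
            {
                "y": np.concatenate([base, fu]),
                "period": [0] * n + [1] * n,
                "subject": list(range(n)) * 2,
            }
        )
        mm = smf.mixedlm("y ~ period", df, groups=df["subject"]).fit(reml=True)
        assert eff == pytest.approx(mm.params["period"], abs=1e-6)
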