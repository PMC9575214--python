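"""Network and edge-wise statistics, permutation inference, FDR."""

import itertools

import numpy as np
import pytest

from fcdiff import (
    ConnectivityDataset,
    EdgeIndexMap,
    GroupFit,
    PermutationPlan,
    PsiModel,
    SCALED_IDENTITY,
    edge_statistic,
    edge_statistics,
    fdr_adjust,
    fit_group,
    network_statistic,
    permutation_test,
)


def _fit(beta, var):
    E = len(beta)
    return GroupFit(beta_hat=np.asarray(beta, float), var_beta=np.asarray(var, float),
                    psi=PsiModel(SCALED_IDENTITY, 0.0), n_iterations=2,
                    converged=True, n_subjects=5)


def _dataset(Y, n1, emap):
    N = Y.shape[0]
    groups = np.array(["g1"] * n1 + ["g2"] * (N - n1), dtype=object)
    ids = [f"s{k}" for k in range(N)]
    return ConnectivityDataset(Y=Y, groups=groups, subject_ids=ids, edge_map=emap)


class TestNetworkStatistic:
    def test_zero_iff_equal_means(self, rng):
        E = 5
        beta = rng.standard_normal(E)
        V = np.eye(E)
        assert network_statistic(_fit(beta, V), _fit(beta, V)) == 0.0
        other = beta + 0.1
        assert network_statistic(_fit(beta, V), _fit(other, V)) > 0.0

    def test_identity_weight_gives_squared_norm(self, rng):
        E = 6
        d = rng.standard_normal(E)
        stat = network_statistic(_fit(d, np.eye(E) / 2), _fit(np.zeros(E), np.eye(E) / 2))
        assert stat == pytest.approx(float(d @ d), rel=1e-12)

    def test_matches_dense_solver_oracle(self, rng):
        emap = EdgeIndexMap(5)
        E = emap.E
        for _ in range(5):
            b1, b2 = rng.standard_normal((2, E))
            A1 = rng.standard_normal((E, E)) * 0.3
            A2 = rng.standard_normal((E, E)) * 0.3
            V1 = A1 @ A1.T + np.eye(E)
            V2 = A2 @ A2.T + np.eye(E)
            stat = network_statistic(_fit(b1, V1), _fit(b2, V2))
            d = b1 - b2
            oracle = float(d @ np.linalg.lstsq(V1 + V2, d, rcond=None)[0])
            assert stat == pytest.approx(oracle, rel=1e-8)


class TestEdgeStatistics:
    def test_arithmetic_example(self):
        f1 = _fit([2.0, 1.0], np.diag([3.0, 1.0]))
        f2 = _fit([0.0, 1.0], np.diag([1.0, 1.0]))
        assert edge_statistic(f1, f2, 0) == pytest.approx(1.0)
        assert edge_statistic(f1, f2, 1) == 0.0

    def test_sum_equals_network_statistic_for_diagonal_variances(self, rng):
        E = 7
        b1, b2 = rng.standard_normal((2, E))
        V1 = np.diag(rng.uniform(0.5, 2.0, E))
        V2 = np.diag(rng.uniform(0.5, 2.0, E))
        f1, f2 = _fit(b1, V1), _fit(b2, V2)
        assert float(np.sum(edge_statistics(f1, f2))) == pytest.approx(
            network_statistic(f1, f2), rel=1e-10
        )

    def test_bad_edge_index_raises(self):
        f = _fit([1.0, 2.0], np.eye(2))
        with pytest.raises(IndexError):
            edge_statistic(f, f, 5)


class TestFdrAdjust:
    def test_hand_worked_stepup_example(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_fixed_points(self):
        np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
        np.testing.assert_allclose(fdr_adjust([0.123]), [0.123])

    def test_matches_literal_stepup_oracle(self, rng):
        def stepup(p):
            m = len(p)
            order = np.argsort(p)
            q = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                idx = order[rank - 1]
                running = min(running, p[idx] * m / rank)
                q[idx] = running
            return q

        for _ in range(20):
            p = rng.uniform(0, 1, size=rng.integers(1, 40))
            np.testing.assert_allclose(fdr_adjust(p), stepup(p), atol=1e-12)

    def test_never_decreases_and_preserves_rejections(self, rng):
        p = rng.uniform(0, 1, 30)
        q = fdr_adjust(p)
        assert np.all(q >= p - 1e-15)
        # step-up rejection set at alpha: compare with direct BH rule
        alpha = 0.2
        order = np.sort(p)
        k = np.flatnonzero(order <= alpha * np.arange(1, 31) / 30)
        n_reject_direct = (k.max() + 1) if k.size else 0
        assert int(np.sum(q <= alpha)) == n_reject_direct

    def test_validates_range(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            fdr_adjust([-0.1])


class TestPermutationTest:
    def test_exhaustive_enumeration_matches_independent_oracle(self, rng):
        """With N1 = N2 = 3 all 20 assignments are enumerated; p must equal
        the direct enumeration computed outside the permutation engine."""
        emap = EdgeIndexMap(4)
        Y = rng.standard_normal((6, emap.E))
        Y[:3] += 0.8
        ds = _dataset(Y, 3, emap)
        Sigma = np.eye(emap.E)
        plan = PermutationPlan(exhaustive=True, seed=0)
        net, table = permutation_test(ds, {"g1": Sigma, "g2": Sigma},
                                      SCALED_IDENTITY, plan)
        assert net.n_permutations == 20

        def stat_for(idx1):
            idx1 = np.asarray(idx1)
            idx2 = np.setdiff1d(np.arange(6), idx1)
            f1 = fit_group(Y[idx1], Sigma, SCALED_IDENTITY)
            f2 = fit_group(Y[idx2], Sigma, SCALED_IDENTITY)
            return network_statistic(f1, f2), edge_statistics(f1, f2)

        obs_net, obs_edge = stat_for([0, 1, 2])
        stats = [stat_for(c) for c in itertools.combinations(range(6), 3)]
        p_net = np.mean([s[0] >= obs_net for s in stats])
        p_edge = np.mean([s[1] >= obs_edge for s in stats], axis=0)
        assert net.statistic == pytest.approx(obs_net, rel=1e-12)
        assert net.p_value == pytest.approx(p_net, abs=1e-12)
        np.testing.assert_allclose(table["p_perm"].to_numpy(), p_edge, atol=1e-12)

    def test_duplicated_groups_cannot_reject(self, rng):
        emap = EdgeIndexMap(4)
        block = rng.standard_normal((4, emap.E))
        Y = np.vstack([block, block])  # the two groups are identical
        ds = _dataset(Y, 4, emap)
        plan = PermutationPlan(B=99, seed=3)
        net, _ = permutation_test(ds, {"g1": np.eye(emap.E), "g2": np.eye(emap.E)},
                                  SCALED_IDENTITY, plan)
        assert net.statistic == pytest.approx(0.0, abs=1e-18)
        assert net.p_value > 0.5

    def test_p_value_invariant_to_group_relabelling(self, rng):
        emap = EdgeIndexMap(4)
        Y = rng.standard_normal((8, emap.E))
        Y[:4] += 0.5
        Sigma = np.eye(emap.E)
        plan = PermutationPlan(exhaustive=True, seed=0)
        ds = _dataset(Y, 4, emap)
        net_a, _ = permutation_test(ds, {"g1": Sigma, "g2": Sigma},
                                    SCALED_IDENTITY, plan)
        # flip which label comes first
        flipped = ConnectivityDataset(
            Y=np.vstack([Y[4:], Y[:4]]),
            groups=np.array(["g2"] * 4 + ["g1"] * 4, dtype=object),
            subject_ids=[f"s{k}" for k in range(8)], edge_map=emap)
        net_b, _ = permutation_test(flipped, {"g1": Sigma, "g2": Sigma},
                                    SCALED_IDENTITY, plan)
        assert net_a.statistic == pytest.approx(net_b.statistic, rel=1e-12)
        assert net_a.p_value == pytest.approx(net_b.p_value, abs=1e-12)

    def test_deterministic_given_seed(self, rng):
        emap = EdgeIndexMap(4)
        Y = rng.standard_normal((8, emap.E))
        ds = _dataset(Y, 4, emap)
        Sigma = np.eye(emap.E)
        plan = PermutationPlan(B=50, seed=12)
        a = permutation_test(ds, {"g1": Sigma, "g2": Sigma}, SCALED_IDENTITY, plan)
        b = permutation_test(ds, {"g1": Sigma, "g2": Sigma}, SCALED_IDENTITY, plan)
        assert a[0].p_value == b[0].p_value
        assert a[1].equals(b[1])

    def test_null_p_values_are_super_uniform(self):
        """Under exchangeable null data P(p <= alpha) <= alpha up to
        Monte-Carlo error, at alpha = 0.05 and 0.1."""
        emap = EdgeIndexMap(5)
        master = np.random.default_rng(99)
        n_reps = 200
        pvals = np.empty(n_reps)
        Sigma = np.eye(emap.E)
        for rep in range(n_reps):
            Y = master.standard_normal((10, emap.E))
            ds = _dataset(Y, 5, emap)
            plan = PermutationPlan(B=60, seed=rep)
            net, _ = permutation_test(ds, {"g1": Sigma, "g2": Sigma},
                                      SCALED_IDENTITY, plan)
            pvals[rep] = net.p_value
        for alpha in (0.05, 0.1):
            rate = float(np.mean(pvals <= alpha))
            bound = alpha + 3 * np.sqrt(alpha * (1 - alpha) / n_reps)
            assert rate <= bound

    def test_permutation_pvalue_bounds(self, rng):
        emap = EdgeIndexMap(4)
        Y = rng.standard_normal((6, emap.E))
        ds = _dataset(Y, 3, emap)
        plan = PermutationPlan(B=19, seed=0)
        net, table = permutation_test(ds, {"g1": np.eye(emap.E), "g2": np.eye(emap.E)},
                                      SCALED_IDENTITY, plan)
        assert 1 / 20 <= net.p_value <= 1.0
        assert np.all(table["p_fdr"].to_numpy() >= table["p_perm"].to_numpy() - 1e-15)

    def test_plan_validation(self):
        with pytest.raises(ValueError):
            PermutationPlan(B=0)
        with pytest.raises(ValueError):
            PermutationPlan(alpha=1.5)
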