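import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netphi import (
    Bipartition,
    DegenerateGraphError,
    InvalidArgumentError,
    TimeSeries,
    WeightedGraph,
    brute_force_mib,
    candidate_partitions,
    enumerate_bipartitions,
    fit_transition_model,
    ncut_value,
    normalized_phi,
    power_adjacency,
    rand_index,
    simulate_var,
    spectral_bipartition,
    spectral_mib,
    threshold_at_percentile,
    watts_strogatz,
)

from conftest import stable_var_model


def two_cliques(k=5, bridge=True):
    n = 2 * k
    W = np.zeros((n, n))
    W[:k, :k] = 1.0
    W[k:, k:] = 1.0
    np.fill_diagonal(W, 0.0)
    if bridge:
        W[k - 1, k] = W[k, k - 1] = 1.0
    return WeightedGraph(weights=W)


class TestEnumerateBipartitions:
    def test_three_channels_give_three_splits(self):
        parts = list(enumerate_bipartitions(3))
        assert len(parts) == 3
        expected = {((0,), (1, 2)), ((0, 1), (2,)), ((0, 2), (1,))}
        assert {(p.group1, p.group2) for p in parts} == expected

    @pytest.mark.parametrize("n", range(2, 13))
    def test_count_and_uniqueness(self, n):
        parts = list(enumerate_bipartitions(n))
        assert len(parts) == 2 ** (n - 1) - 1
        assert len({(p.group1, p.group2) for p in parts}) == len(parts)

    def test_twenty_channels_count(self):
        assert sum(1 for _ in enumerate_bipartitions(20)) == 524_287

    @pytest.mark.parametrize("n", [1, 0, 26])
    def test_out_of_range_rejected(self, n):
        with pytest.raises(InvalidArgumentError):
            list(enumerate_bipartitions(n))


class TestBruteForceMIB:
    def test_finds_the_analytic_zero_cut(self):
        from netphi import GaussianTransitionModel

        B = np.array([[0.5, 0.35], [0.25, 0.45]])
        A = np.zeros((4, 4))
        A[:2, :2], A[2:, 2:] = B, 0.9 * B
        model = GaussianTransitionModel.from_var_coefficients(A)
        result = brute_force_mib(model)
        assert result.best.partition == Bipartition([0, 1], [2, 3])
        assert result.best.phi_bits == pytest.approx(0.0, abs=1e-6)

    def test_enumeration_order_does_not_change_the_minimizer(self):
        model = stable_var_model(21, n=8, scale=0.15)
        result = brute_force_mib(model)
        # independent rescoring in reversed enumeration order
        best_val, best_part = np.inf, None
        for part in reversed(list(enumerate_bipartitions(8))):
            r = normalized_phi(model, part)
            if r.valid and r.normalized_phi < best_val - 1e-15:
                best_val, best_part = r.normalized_phi, part
        assert result.best.partition == best_part
        assert result.best.normalized_phi == pytest.approx(best_val, abs=1e-12)

    def test_minimum_dominates_random_bipartitions(self):
        model = stable_var_model(22, n=7, scale=0.2)
        result = brute_force_mib(model)
        rng = np.random.default_rng(0)
        for _ in range(50):
            labels = np.zeros(7, dtype=int)
            labels[rng.choice(7, rng.integers(1, 7), replace=False)] = 1
            if labels.min() == labels.max():
                continue
            r = normalized_phi(model, Bipartition.from_labels(labels))
            assert result.best.normalized_phi <= r.normalized_phi + 1e-12

    def test_refuses_oversized_systems(self):
        model = stable_var_model(23, n=4)
        big = model.A  # only the channel count matters for the guard
        from netphi import GaussianTransitionModel

        fake = GaussianTransitionModel(
            tau=1,
            Sigma_past=np.eye(19), Sigma_present=np.eye(19),
            Sigma_cross=np.zeros((19, 19)), A=np.zeros((19, 19)),
            Sigma_E=np.eye(19),
        )
        with pytest.raises(InvalidArgumentError, match="spectral"):
            brute_force_mib(fake)
        del big


class TestPowerAdjacency:
    def test_endpoint_values(self):
        corr = np.array([[1.0, 1.0, -1.0], [1.0, 1.0, 0.0], [-1.0, 0.0, 1.0]])
        for beta in (1.0, 3.5, 10.0):
            W = power_adjacency(corr, beta).weights
            assert W[0, 1] == pytest.approx(1.0)
            assert W[0, 2] == pytest.approx(0.0)
        assert power_adjacency(corr, 1.0).weights[1, 2] == pytest.approx(0.5)

    def test_out_of_range_correlations_rejected(self):
        bad = np.array([[1.0, 1.5], [1.5, 1.0]])
        with pytest.raises(InvalidArgumentError):
            power_adjacency(bad, 2.0)


class TestThresholdAtPercentile:
    def test_zeroth_percentile_is_identity(self):
        g = two_cliques()
        out = threshold_at_percentile(g, 0.0)
        assert np.array_equal(out.weights, g.weights)

    def test_median_cut_zeroes_exactly_the_smallest_half(self):
        W = np.zeros((4, 4))
        vals = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        iu = np.triu_indices(4, k=1)
        W[iu] = vals
        W = W + W.T
        out = threshold_at_percentile(WeightedGraph(weights=W), 0.5)
        kept = sorted(out.weights[iu][out.weights[iu] > 0])
        assert kept == [0.4, 0.5, 0.6]

    @pytest.mark.parametrize("pct", [-0.01, 0.991, 1.0])
    def test_out_of_range_percentile_rejected(self, pct):
        with pytest.raises(InvalidArgumentError):
            threshold_at_percentile(two_cliques(), pct)


class TestSpectralBipartition:
    def test_separates_disconnected_cliques(self):
        g = two_cliques(bridge=False)
        part = spectral_bipartition(g, seed=0)
        assert part == Bipartition(range(5), range(5, 10))
        assert ncut_value(g, part) == 0.0

    def test_severs_the_bridge_between_cliques(self):
        g = two_cliques(bridge=True)
        part = spectral_bipartition(g, seed=0)
        assert part == Bipartition(range(5), range(5, 10))

    def test_all_zero_graph_rejected(self):
        with pytest.raises(DegenerateGraphError):
            spectral_bipartition(WeightedGraph(weights=np.zeros((4, 4))), 0)

    def test_near_optimal_ncut_on_random_graphs(self):
        import networkx as nx

        hits, ratios = 0, []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            while True:  # connected random weighted graph, ~40% edge density
                W = np.triu(
                    (rng.random((10, 10)) < 0.4)
                    * rng.uniform(0.2, 1.0, (10, 10)),
                    k=1,
                )
                W = W + W.T
                if W.any() and nx.is_connected(nx.from_numpy_array(W)):
                    break
            g = WeightedGraph(weights=W)
            part = spectral_bipartition(g, seed=seed)
            val = ncut_value(g, part)
            best = min(ncut_value(g, p) for p in enumerate_bipartitions(10))
            ratios.append(val / best if best > 0 else 1.0)
            hits += val <= best + 1e-12
        assert hits >= 40  # exact minimum in >= 80% of seeds
        assert max(ratios) <= 1.5


class TestNcutValue:
    def test_disconnected_components_cut_freely(self):
        g = two_cliques(bridge=False)
        assert ncut_value(g, Bipartition(range(5), range(5, 10))) == 0.0

    def test_complete_graph_hand_count(self):
        W = np.ones((4, 4)) - np.eye(4)
        g = WeightedGraph(weights=W)
        # cut = 4 crossing edges, assoc = 6 endpoints-weight per side
        assert ncut_value(g, Bipartition([0, 1], [2, 3])) == pytest.approx(4 / 6 + 4 / 6)

    def test_label_swap_symmetry(self):
        g = two_cliques()
        p = Bipartition([0, 1, 2], [3, 4, 5, 6, 7, 8, 9])
        q = Bipartition([3, 4, 5, 6, 7, 8, 9], [0, 1, 2])
        assert ncut_value(g, p) == ncut_value(g, q)

    def test_zero_iff_nothing_crosses(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            W = np.triu((rng.random((8, 8)) < 0.4) * rng.random((8, 8)), k=1)
            W = W + W.T
            if not W.any():
                continue
            g = WeightedGraph(weights=W)
            for pseed in range(3):
                labels = np.zeros(8, int)
                labels[rng.choice(8, rng.integers(1, 8), replace=False)] = 1
                if labels.min() == labels.max():
                    continue
                p = Bipartition.from_labels(labels)
                crossing = W[np.ix_(p.group1, p.group2)].sum()
                assert (ncut_value(g, p) == 0.0) == (crossing == 0.0)


class TestCandidatePartitions:
    def test_default_grid_generates_2189_candidates(self):
        rng = np.random.default_rng(40)
        corr = np.corrcoef(rng.standard_normal((400, 20)), rowvar=False)
        cset = candidate_partitions(corr, seed=0)
        assert cset.n_generated == 2189

    def test_planted_two_block_structure_survives(self):
        rng = np.random.default_rng(41)
        base = rng.standard_normal((2_000, 2))
        noise = 0.05 * rng.standard_normal((2_000, 10))
        data = np.column_stack([base[:, [0]] * np.ones(5), base[:, [1]] * np.ones(5)])
        corr = np.corrcoef(data + noise, rowvar=False)
        cset = candidate_partitions(corr, seed=1)
        assert Bipartition(range(5), range(5, 10)) in cset.partitions()

    def test_unique_count_matches_direct_dedup(self):
        rng = np.random.default_rng(42)
        corr = np.corrcoef(rng.standard_normal((300, 8)), rowvar=False)
        cset = candidate_partitions(corr, seed=2, n_beta=4, pct_step=0.05)
        seen = []
        for p in cset.partitions():
            assert all(p != q for q in seen)
            seen.append(p)
        assert cset.n_unique == len(seen)

    def test_deterministic_given_corr_and_seed(self):
        rng = np.random.default_rng(43)
        corr = np.corrcoef(rng.standard_normal((300, 6)), rowvar=False)
        a = candidate_partitions(corr, seed=3, n_beta=4, pct_step=0.05)
        b = candidate_partitions(corr, seed=3, n_beta=4, pct_step=0.05)
        assert a.partitions() == b.partitions()
        assert a.n_generated == b.n_generated

    def test_too_few_channels_rejected(self):
        with pytest.raises(InvalidArgumentError):
            candidate_partitions(np.eye(2), seed=0)


class TestSpectralMIB:
    def test_never_beats_brute_force_and_usually_matches(self):
        hits = 0
        for seed in range(5):
            graph = watts_strogatz(10, 4, 0.2, seed=seed)
            ts = simulate_var(graph, coupling=0.6, n_points=20_000, seed=seed)
            model = fit_transition_model(ts, 1)
            brute = brute_force_mib(model)
            spec = spectral_mib(
                ts, 1, seed=seed, model=model, n_beta=4, pct_step=0.02
            )
            assert spec.best.normalized_phi >= brute.best.normalized_phi - 1e-9
            hits += spec.best.normalized_phi <= brute.best.normalized_phi + 1e-9
        assert hits >= 3

    def test_reports_per_candidate_table(self):
        rng = np.random.default_rng(50)
        data = rng.standard_normal((5_000, 5))
        data[1:] += 0.5 * data[:-1]
        ts = TimeSeries(data=data)
        res = spectral_mib(ts, 1, seed=0, n_beta=3, pct_step=0.1)
        assert res.method == "spectral"
        assert len(res.table) >= res.n_evaluated
        valid = res.table[res.table["valid"]]
        assert res.best.normalized_phi == pytest.approx(
            valid["normalized_phi"].min()
        )


class TestRandIndex:
    def test_identical_partitions_score_one(self):
        p = Bipartition([0, 1, 2], [3, 4, 5])
        assert rand_index(p, p) == 1.0

    def test_label_swap_invariance(self):
        p = Bipartition([0, 1, 2], [3, 4, 5])
        q = Bipartition([3, 4, 5], [0, 1, 2])
        assert rand_index(p, q) == 1.0

    def test_hand_counted_pair_agreement(self):
        p = Bipartition([0, 1, 2], [3, 4, 5])
        q = Bipartition([0, 1], [2, 3, 4, 5])
        assert rand_index(p, q) == pytest.approx(10 / 15)

    def test_mismatched_channel_sets_rejected(self):
        with pytest.raises(InvalidArgumentError):
            rand_index(Bipartition([0], [1]), Bipartition([0], [1, 2]))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        labels1=st.lists(st.integers(0, 1), min_size=4, max_size=12),
        labels2=st.lists(st.integers(0, 1), min_size=4, max_size=12),
    )
    def test_symmetric_bounded_and_one_iff_equal(self, labels1, labels2):
        n = min(len(labels1), len(labels2))
        l1, l2 = np.array(labels1[:n]), np.array(labels2[:n])
        if l1.min() == l1.max() or l2.min() == l2.max():
            return
        p, q = Bipartition.from_labels(l1), Bipartition.from_labels(l2)
        r = rand_index(p, q)
        assert 0.0 <= r <= 1.0
        assert r == rand_index(q, p)
        assert (r == 1.0) == (p == q)
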