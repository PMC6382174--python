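import numpy as np
import pytest
from scipy.linalg import solve_discrete_lyapunov

from netphi import (
    Bipartition,
    GaussianTransitionModel,
    InvalidArgumentError,
    TimeSeries,
    fit_transition_model,
    mutual_information_time,
    normalization_K,
    normalized_phi,
    phi_g,
    select_time_lag,
)
from netphi.gaussian_model import gaussian_entropy

from conftest import stable_var_model


def grid_search_phi(model, partition, radius=1.5, points=9, rounds=12):
    """Independent oracle: multi-resolution dense grid search over the free
    (within-block) entries of the disconnected regression matrix."""
    labels = partition.labels(model.n_channels)
    mask = labels[:, None] == labels[None, :]
    free = np.argwhere(mask)
    A, S, SE = model.A, model.Sigma_past, model.Sigma_E
    center = A[mask].astype(float)
    width = radius
    p = free.shape[0]
    grids = [np.linspace(-1, 1, points)] * p
    best = None
    for _ in range(rounds):
        axes = [center[k] + width * grids[k] for k in range(p)]
        mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, p)
        D = np.broadcast_to(A, (mesh.shape[0],) + A.shape).copy()
        for k, (i, j) in enumerate(free):
            D[:, i, j] = A[i, j] - mesh[:, k]
        M = SE + np.einsum("bij,jk,blk->bil", D, S, D)
        sign, logdet = np.linalg.slogdet(M)
        logdet[sign <= 0] = np.inf
        idx = int(np.argmin(logdet))
        best = 0.5 * (logdet[idx] - np.linalg.slogdet(SE)[1]) / np.log(2)
        center = mesh[idx]
        width *= 0.5
    return best


class TestPhiG:
    def test_block_diagonal_model_has_zero_phi(self):
        B = np.array([[0.5, 0.3], [0.2, 0.4]])
        A = np.zeros((4, 4))
        A[:2, :2], A[2:, 2:] = B, 0.8 * B
        model = GaussianTransitionModel.from_var_coefficients(A)
        result = phi_g(model, Bipartition([0, 1], [2, 3]))
        assert result.phi_bits == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(result.A_prime, A, atol=1e-6)

    def test_two_channel_grid_oracle(self):
        A = np.array([[0.8, 0.4], [0.0, 0.7]])
        S = solve_discrete_lyapunov(A, np.eye(2))
        model = GaussianTransitionModel(
            tau=1, Sigma_past=S, Sigma_present=S.copy(),
            Sigma_cross=A @ S, A=A, Sigma_E=np.eye(2),
        )
        part = Bipartition([0], [1])
        result = phi_g(model, part)
        # dense 1e-3 grid over the two diagonal entries of A'
        a = np.arange(-0.5, 1.5, 1e-3)
        aa, bb = np.meshgrid(a, a, indexing="ij")
        d11, d12, d21, d22 = A[0, 0] - aa, A[0, 1], A[1, 0], A[1, 1] - bb
        s11, s12, s22 = S[0, 0], S[0, 1], S[1, 1]
        m11 = 1 + d11 * (d11 * s11 + d12 * s12) + d12 * (d11 * s12 + d12 * s22)
        m12 = d21 * (d11 * s11 + d12 * s12) + d22 * (d11 * s12 + d12 * s22)
        m22 = 1 + d21 * (d21 * s11 + d22 * s12) + d22 * (d21 * s12 + d22 * s22)
        oracle = 0.5 * np.log2(m11 * m22 - m12**2).min()
        assert result.phi_bits == pytest.approx(oracle, abs=1e-4)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_grid_oracle_on_random_two_channel_models(self, seed):
        model = stable_var_model(seed, n=2, scale=0.35)
        result = phi_g(model, Bipartition([0], [1]))
        oracle = grid_search_phi(model, Bipartition([0], [1]))
        assert result.phi_bits == pytest.approx(oracle, abs=1e-4)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_grid_oracle_on_random_three_channel_models(self, seed):
        model = stable_var_model(100 + seed, n=3, scale=0.3)
        part = Bipartition([0], [1, 2])
        result = phi_g(model, part)
        oracle = grid_search_phi(model, part, points=7)
        assert result.phi_bits == pytest.approx(oracle, abs=1e-4)

    def test_off_block_entries_of_a_prime_are_exactly_zero(self):
        model = stable_var_model(7, n=5)
        part = Bipartition([0, 2], [1, 3, 4])
        result = phi_g(model, part)
        labels = part.labels(5)
        off = labels[:, None] != labels[None, :]
        assert np.all(result.A_prime[off] == 0.0)

    def test_disconnected_residual_dominates_full_residual(self):
        model = stable_var_model(8, n=5)
        result = phi_g(model, Bipartition([0, 1], [2, 3, 4]))
        gap = result.Sigma_Eprime - model.Sigma_E
        assert np.linalg.eigvalsh(0.5 * (gap + gap.T))[0] > -1e-8

    def test_phi_bounded_by_temporal_mutual_information(self):
        for seed in range(8):
            model = stable_var_model(200 + seed, n=5)
            mi = mutual_information_time(model)
            for part in (
                Bipartition([0], [1, 2, 3, 4]),
                Bipartition([0, 1], [2, 3, 4]),
                Bipartition([0, 2, 4], [1, 3]),
            ):
                phi = phi_g(model, part).phi_bits
                assert -1e-9 <= phi <= mi + 1e-6

    def test_zero_phi_iff_off_block_coupling_absent(self):
        part = Bipartition([0, 1], [2, 3])
        B = np.array([[0.5, 0.3], [0.2, 0.4]])
        A_disc = np.zeros((4, 4))
        A_disc[:2, :2], A_disc[2:, 2:] = B, B
        disc = GaussianTransitionModel.from_var_coefficients(A_disc)
        assert phi_g(disc, part).phi_bits == pytest.approx(0.0, abs=1e-6)
        A_coupled = A_disc.copy()
        A_coupled[0, 3] = 0.3
        coupled = GaussianTransitionModel.from_var_coefficients(A_coupled)
        assert phi_g(coupled, part).phi_bits > 1e-3

    def test_scale_invariance_of_phi(self):
        rng = np.random.default_rng(13)
        data = rng.standard_normal((20_000, 4)) @ rng.normal(size=(4, 4))
        data[1:] += 0.4 * data[:-1]
        part = Bipartition([0, 1], [2, 3])
        phi_a = phi_g(fit_transition_model(TimeSeries(data=data), 1), part).phi_bits
        scaled = data.copy()
        scaled[:, 2] *= 37.5
        phi_b = phi_g(fit_transition_model(TimeSeries(data=scaled), 1), part).phi_bits
        assert abs(phi_a - phi_b) < 1e-6

    def test_never_worse_than_block_diagonal_initialization(self):
        for seed in range(5):
            model = stable_var_model(300 + seed, n=6, scale=0.25)
            part = Bipartition([0, 1, 2], [3, 4, 5])
            labels = part.labels(6)
            mask = labels[:, None] == labels[None, :]
            A_init = np.where(mask, model.A, 0.0)
            D = model.A - A_init
            M = model.Sigma_E + D @ model.Sigma_past @ D.T
            f_init = 0.5 * (
                np.linalg.slogdet(M)[1] - np.linalg.slogdet(model.Sigma_E)[1]
            ) / np.log(2)
            assert phi_g(model, part).phi_bits <= f_init + 1e-12


class TestNormalizationK:
    def test_identity_covariance_split_evenly(self):
        K = normalization_K(np.eye(4), Bipartition([0, 1], [2, 3]))
        assert K == pytest.approx(gaussian_entropy(np.eye(2)))
        assert K == pytest.approx(np.log2(2 * np.pi * np.e))

    def test_equals_smaller_marginal_entropy(self):
        rng = np.random.default_rng(14)
        B = rng.normal(size=(6, 6))
        Sigma = B @ B.T + np.eye(6)
        part = Bipartition([0, 1], [2, 3, 4, 5])
        expected = min(
            gaussian_entropy(Sigma[np.ix_([0, 1], [0, 1])]),
            gaussian_entropy(Sigma[np.ix_([2, 3, 4, 5], [2, 3, 4, 5])]),
        )
        assert normalization_K(Sigma, part) == pytest.approx(expected)

    def test_near_constant_channel_flags_partition_invalid(self):
        Sigma = np.diag([1e-30, 1.0, 1.0])
        model = GaussianTransitionModel(
            tau=1, Sigma_past=Sigma, Sigma_present=Sigma.copy(),
            Sigma_cross=np.zeros((3, 3)), A=np.zeros((3, 3)),
            Sigma_E=Sigma.copy(),
        )
        result = normalized_phi(model, Bipartition([0], [1, 2]))
        assert not result.valid
        assert np.isnan(result.normalized_phi)


class TestNormalizedPhi:
    def test_definition_consistency(self):
        model = stable_var_model(15, n=4)
        result = normalized_phi(model, Bipartition([0, 1], [2, 3]))
        assert result.normalized_phi * result.K_bits == pytest.approx(
            result.phi_bits, abs=1e-9
        )

    def test_block_diagonal_model_normalizes_to_zero(self):
        A = np.zeros((4, 4))
        A[:2, :2] = A[2:, 2:] = 0.5 * np.eye(2)
        model = GaussianTransitionModel.from_var_coefficients(A)
        result = normalized_phi(model, Bipartition([0, 1], [2, 3]))
        assert result.normalized_phi == pytest.approx(0.0, abs=1e-6)


class TestBipartition:
    def test_canonical_form_swaps_groups(self):
        p = Bipartition([3, 2], [0, 1])
        assert p.group1 == (0, 1)
        assert p.group2 == (2, 3)

    @pytest.mark.parametrize(
        "g1,g2", [([], [0, 1]), ([0], [0, 1]), ([0, 0], [1])]
    )
    def test_invalid_groups_rejected(self, g1, g2):
        with pytest.raises(InvalidArgumentError):
            Bipartition(g1, g2)

    def test_labels_roundtrip(self):
        p = Bipartition([0, 3], [1, 2])
        assert Bipartition.from_labels(p.labels(4)) == p


class TestSelectTimeLag:
    def test_finds_the_true_driving_delay(self):
        rng = np.random.default_rng(16)
        m = 30_000
        x1 = np.zeros(m)
        for t in range(1, m):
            x1[t] = 0.7 * x1[t - 1] + rng.standard_normal()
        x2 = np.zeros(m)
        x2[2:] = 0.9 * x1[:-2]
        x2 += 0.5 * rng.standard_normal(m)
        ts = TimeSeries(data=np.column_stack([x1, x2]))
        tau_star, table = select_time_lag(ts, [1, 2, 3])
        assert tau_star == 2
        assert not table.attrs["all_near_zero"]

    def test_white_noise_flags_all_near_zero(self):
        ts = TimeSeries(data=np.random.default_rng(17).standard_normal((20_000, 3)))
        with pytest.warns(RuntimeWarning, match="below 0.01 bits"):
            tau_star, table = select_time_lag(ts, [1, 2])
        assert table.attrs["all_near_zero"]
        assert (table["phi_bits"] < 0.01).all()

    def test_empty_lag_list_rejected(self):
        ts = TimeSeries(data=np.random.default_rng(18).standard_normal((100, 2)))
        with pytest.raises(InvalidArgumentError):
            select_time_lag(ts, [])
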