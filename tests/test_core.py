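import numpy as np
import pytest

import ccssp
from ccssp import (
    EEGEpochs,
    NumericalError,
    ParameterError,
    SpatialSpectralModel,
    ValidationError,
    class_covariances,
    extract_features,
    solve_regularized_gevd,
)
from ccssp.delay_embedding import embed
from helpers import reference_regularized_csp


def _epochs(data, labels, fs=100.0):
    data = np.asarray(data, dtype=float)
    return EEGEpochs(
        data=data, labels=labels, fs=fs,
        channel_names=[f"ch{c}" for c in range(data.shape[1])],
    )


class TestClassCovariances:
    def test_hand_computed_outer_product(self):
        # X = [[1,-1],[1,1]] -> X X' = 2 I -> trace-normalized 0.5 I
        ep = _epochs(
            [[[1.0, -1.0], [1.0, 1.0]], [[1.0, -1.0], [1.0, 1.0]]], [1, 2]
        )
        S1, S2 = class_covariances(embed(ep, 0))
        expected = np.array([[0.5, 0.0], [0.0, 0.5]])
        assert np.allclose(S1.matrix, expected, atol=1e-14)
        assert np.allclose(S2.matrix, expected, atol=1e-14)

    def test_trace_one_and_symmetry(self, mi_epochs):
        S1, S2 = class_covariances(embed(mi_epochs, 3))
        for S in (S1, S2):
            assert abs(np.trace(S.matrix) - 1.0) < 1e-12
            assert np.allclose(S.matrix, S.matrix.T, atol=1e-12)

    def test_duplicating_trials_leaves_covariance_unchanged(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((4, 3, 20))
        ep = _epochs(X, [1, 1, 2, 2])
        dup = _epochs(
            np.concatenate([X, X[:2]]), [1, 1, 2, 2, 1, 1]
        )
        a, _ = class_covariances(embed(ep, 0))
        b, _ = class_covariances(embed(dup, 0))
        assert np.allclose(a.matrix, b.matrix, atol=1e-14)

    def test_missing_condition_rejected(self):
        ep = _epochs(np.random.default_rng(1).standard_normal((3, 2, 10)),
                     [1, 1, 1])
        with pytest.raises(ValidationError, match="two classes"):
            class_covariances(embed(ep, 0))

    def test_zero_power_trial_rejected(self):
        data = np.random.default_rng(2).standard_normal((2, 2, 10))
        data[1] = 0.0
        ep = _epochs(data, [1, 2])
        with pytest.raises(ValidationError, match="zero total power"):
            class_covariances(embed(ep, 0))


class TestSolveRegularizedGevd:
    def test_diagonal_closed_form(self):
        vals, vecs = solve_regularized_gevd(
            np.diag([0.4, 0.1]), np.diag([0.1, 0.4]), 0.0
        )
        assert np.allclose(vals, [0.8, 0.2], atol=1e-12)
        assert np.allclose(np.abs(vecs), np.eye(2), atol=1e-12)

    def test_regularizer_dominated_limit(self):
        rng = np.random.default_rng(0)
        M = rng.standard_normal((5, 5))
        S1 = M @ M.T
        S1 /= np.trace(S1)
        S2 = np.eye(5) / 5
        vals, _ = solve_regularized_gevd(S1, S2, 1e6)
        assert np.allclose(vals, 0.5, atol=1e-5)

    def test_complementarity_of_role_swap(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            A = rng.standard_normal((4, 4))
            B = rng.standard_normal((4, 4))
            S1 = A @ A.T / np.trace(A @ A.T)
            S2 = B @ B.T / np.trace(B @ B.T)
            v1, _ = solve_regularized_gevd(S1, S2, 1e-3)
            v2, _ = solve_regularized_gevd(S2, S1, 1e-3)
            assert np.all(v1 > 0) and np.all(v1 < 1)
            assert np.allclose(v1, (1 - v2)[::-1], atol=1e-10)

    def test_singular_composite_needs_regularization(self):
        v = np.array([1.0, 2.0, -1.0])
        S = np.outer(v, v)
        S /= np.trace(S)  # rank 1, so S + S is singular
        with pytest.raises(NumericalError, match="singular"):
            solve_regularized_gevd(S, S, 0.0)
        vals, _ = solve_regularized_gevd(S, S, 1e-5)  # regularized is fine
        assert np.all((vals > 0) & (vals < 1))

    def test_asymmetric_input_rejected(self):
        M = np.array([[1.0, 0.5], [0.0, 1.0]])
        with pytest.raises(ValidationError, match="symmetric"):
            solve_regularized_gevd(M, np.eye(2), 1e-3)


class TestFit:
    def test_model_invariants(self, fitted_model):
        m = fitted_model
        lead, trail = m.eigvals[: m.m], m.eigvals[m.m :]
        assert np.all(np.diff(lead) <= 0)       # descending
        assert np.all(np.diff(trail) >= 0)      # ascending
        assert np.all((m.eigvals > 0) & (m.eigvals < 1))
        assert np.allclose(np.linalg.norm(m.W, axis=0), 1.0, atol=1e-12)
        piv = np.abs(m.W).argmax(axis=0)
        assert np.all(m.W[piv, np.arange(m.W.shape[1])] > 0)

    def test_too_many_pairs_rejected(self, mi_epochs):
        with pytest.raises(ParameterError, match="m"):
            ccssp.fit(mi_epochs, k=0, m=5)  # 2m = 10 > D = 8

    @pytest.mark.parametrize("seed", range(3))
    def test_k0_reduces_to_reference_csp(self, seed):
        from ccssp import synthetic

        ep, _ = synthetic.generate(
            synthetic.reseed(synthetic.scenario("b"), 300 + seed)
        )
        model = ccssp.fit(ep, k=0, epsilon=1e-5, m=3)
        feats = extract_features(model, ep).values
        W_ref, vals_ref, feats_ref = reference_regularized_csp(ep, 1e-5, 3)
        assert np.allclose(model.W, W_ref, atol=1e-10)
        assert np.allclose(model.eigvals, vals_ref, atol=1e-10)
        assert np.allclose(feats, feats_ref, atol=1e-10)

    def test_channel_permutation_equivariance(self, mi_epochs):
        ep = mi_epochs.subset(range(40))
        perm = np.array([3, 0, 5, 1, 7, 2, 6, 4])
        permuted = EEGEpochs(
            data=ep.data[:, perm, :],
            labels=ep.labels,
            fs=ep.fs,
            channel_names=[ep.channel_names[p] for p in perm],
        )
        k, C = 2, 8
        a = ccssp.fit(ep, k=k, epsilon=1e-4, m=2)
        b = ccssp.fit(permuted, k=k, epsilon=1e-4, m=2)
        assert np.allclose(a.eigvals, b.eigvals, atol=1e-10)
        # each delay block of every column is permuted identically
        for blk in range(2 * k + 1):
            rows = slice(blk * C, (blk + 1) * C)
            assert np.allclose(
                a.W[rows, :][perm, :], b.W[rows, :], atol=1e-8
            )

    def test_regularization_pulls_eigvals_to_half(self, mi_epochs):
        ep = mi_epochs.subset(range(40))
        devs = []
        for eps in [1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1.0]:
            model = ccssp.fit(ep, k=1, epsilon=eps, m=2)
            devs.append(np.abs(model.eigvals - 0.5).max())
        assert all(d2 <= d1 + 1e-12 for d1, d2 in zip(devs, devs[1:]))

    def test_label_mapping_smaller_is_condition_one(self):
        """Relabeling (1,2) -> (0,1) leaves the fitted filters unchanged."""
        rng = np.random.default_rng(9)
        X = rng.standard_normal((20, 4, 50))
        a = ccssp.fit(_epochs(X, [1] * 10 + [2] * 10), k=1, m=2)
        b = ccssp.fit(_epochs(X, [0] * 10 + [1] * 10), k=1, m=2)
        assert np.array_equal(a.W, b.W)


class TestExtractFeatures:
    def test_scaling_shifts_by_twice_log_factor(self, fitted_model, mi_epochs):
        ep = mi_epochs.subset(range(6))
        scaled = EEGEpochs(
            data=3.0 * ep.data, labels=ep.labels, fs=ep.fs,
            channel_names=ep.channel_names,
        )
        f0 = extract_features(fitted_model, ep).values
        f1 = extract_features(fitted_model, scaled).values
        assert np.allclose(f1 - f0, 2 * np.log(3.0), atol=1e-10)

    def test_unit_filter_recovers_log_noise_variance(self):
        """A one-channel unit filter on white noise of variance 4 gives a
        feature near ln 4, within the sampling error of log sample variance."""
        T = 500
        rng = np.random.default_rng(10)
        data = 2.0 * rng.standard_normal((30, 2, T))
        ep = _epochs(data, [1] * 15 + [2] * 15)
        model = SpatialSpectralModel(
            W=np.eye(2), eigvals=np.array([0.6, 0.4]), k=0, epsilon=1e-5,
            m=1, n_channels=2, channel_names=["a", "b"], fs=100.0,
        )
        feats = extract_features(model, ep).values[:, 0]
        tol = 3 * np.sqrt(2 / (T - 1))
        assert abs(feats.mean() - np.log(4.0)) < tol

    def test_zero_trial_is_an_error_not_minus_inf(self, fitted_model, mi_epochs):
        ep = mi_epochs.subset(range(2))
        data = ep.data.copy()
        data[1] = 0.0
        bad = EEGEpochs(data=data, labels=ep.labels, fs=ep.fs,
                        channel_names=ep.channel_names)
        with pytest.raises(ValidationError, match="zero"):
            extract_features(fitted_model, bad)

    def test_channel_count_mismatch(self, fitted_model):
        ep = _epochs(np.random.default_rng(0).standard_normal((2, 3, 50)),
                     [1, 2])
        with pytest.raises(ValidationError, match="channels"):
            extract_features(fitted_model, ep)


class TestSerialization:
    def test_round_trip(self, fitted_model, tmp_path):
        path = tmp_path / "model.json"
        ccssp.save_model(fitted_model, path)
        back = ccssp.load_model(path)
        assert np.array_equal(back.W, fitted_model.W)
        assert np.array_equal(back.eigvals, fitted_model.eigvals)
        assert back.k == fitted_model.k
        assert back.epsilon == fitted_model.epsilon
        assert back.channel_names == fitted_model.channel_names

    def test_deterministic_bytes(self, fitted_model, tmp_path):
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        ccssp.save_model(fitted_model, p1)
        ccssp.save_model(fitted_model, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_field_rejected(self, tmp_path):
        import json

        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"k": 1}))
        with pytest.raises(ValidationError, match="missing field"):
            ccssp.load_model(path)
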