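"""Tensor algebra and the nonnegative Tucker decomposition."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from sklearn.base import clone

from trilink import (NonnegativeTucker, fold, n_mode_product,
                     planted_tucker_tensor, tucker_to_tensor, unfold)
from trilink.tucker import update_core, update_factor


def _loop_n_mode(tensor, matrix, mode):
    shape = list(tensor.shape)
    shape[mode] = matrix.shape[0]
    out = np.zeros(shape)
    for idx in np.ndindex(*shape):
        src = list(idx)
        for r in range(tensor.shape[mode]):
            src[mode] = r
            out[idx] += matrix[idx[mode], r] * tensor[tuple(src)]
    return out


class TestUnfold:
    def test_all_ones_tensor(self):
        assert unfold(np.ones((2, 2, 2)), 0).tolist() == [[1.0] * 4] * 2

    def test_unfold_fold_roundtrip(self, rng):
        t = rng.random((3, 4, 5))
        for mode in range(3):
            assert np.array_equal(fold(unfold(t, mode), mode, t.shape), t)

    def test_kronecker_identity_all_modes(self, rng):
        """unfold(G x1 Z1 x2 Z2 x3 Z3, n) = Zn G(n) (kron of others).T"""
        g = rng.random((2, 3, 2))
        zs = [rng.random((4, 2)), rng.random((5, 3)), rng.random((6, 2))]
        full = tucker_to_tensor(g, zs)
        for mode in range(3):
            others = [zs[m] for m in range(3) if m != mode]
            expected = zs[mode] @ unfold(g, mode) @ np.kron(*others).T
            assert np.allclose(unfold(full, mode), expected, atol=1e-10)


class TestNModeProduct:
    def test_identity_matrix_is_noop(self, rng):
        t = rng.random((3, 4, 5))
        for mode in range(3):
            m = np.eye(t.shape[mode])
            assert np.allclose(n_mode_product(t, m, mode), t)

    def test_zero_matrix_gives_zero_tensor(self, rng):
        t = rng.random((3, 3, 3))
        assert np.all(n_mode_product(t, np.zeros((2, 3)), 1) == 0)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            n_mode_product(rng.random((3, 3, 3)), rng.random((2, 4)), 0)

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(5):
            t = rng.random((3, 3, 3))
            for mode in range(3):
                m = rng.random((2, 3))
                assert np.allclose(n_mode_product(t, m, mode),
                                   _loop_n_mode(t, m, mode), atol=1e-12)


class TestMultiplicativeUpdates:
    def test_factor_update_fixed_point_on_exact_model(self):
        t, core, factors = planted_tucker_tensor((4, 5, 6), (2, 2, 2), seed=3)
        for mode in range(3):
            before = factors[mode].copy()
            update_factor(t, core, [f.copy() if i != mode else factors[i]
                                    for i, f in enumerate(factors)], mode)
            assert np.allclose(factors[mode], before, atol=1e-8)

    def test_core_update_fixed_point_on_exact_model(self):
        t, core, factors = planted_tucker_tensor((4, 5, 6), (2, 2, 2), seed=4)
        before = core.copy()
        update_core(t, core, factors)
        assert np.allclose(core, before, atol=1e-8)

    def test_zero_entries_are_absorbing(self, rng):
        t = rng.random((4, 4, 4))
        factors = [rng.random((4, 2)) for _ in range(3)]
        core = rng.random((2, 2, 2))
        factors[0][1, :] = 0.0
        core[0, 1, 1] = 0.0
        update_factor(t, core, factors, 0)
        update_core(t, core, factors)
        assert np.all(factors[0][1, :] == 0.0)
        assert core[0, 1, 1] == 0.0

    def test_factor_update_does_not_increase_unfolded_residual(self, rng):
        for _ in range(10):
            t = rng.random((4, 4, 4))
            factors = [rng.uniform(0.1, 1.1, (4, 2)) for _ in range(3)]
            core = rng.uniform(0.1, 1.1, (2, 2, 2))
            from trilink.tucker import _factor_surrogate
            s = _factor_surrogate(core, factors, 0)
            before = np.linalg.norm(unfold(t, 0) - factors[0] @ s)
            update_factor(t, core, factors, 0)
            after = np.linalg.norm(unfold(t, 0) - factors[0] @ s)
            assert after <= before + 1e-12

    def test_core_update_matches_kronecker_vec_oracle(self, rng):
        """Gram-form core step equals the vectorised NMF update with
        Q = Z3 (x) Z2 (x) Z1 acting on Fortran-order vec."""
        for _ in range(5):
            t = rng.random((2, 2, 2))
            factors = [rng.uniform(0.1, 1.1, (2, 2)) for _ in range(3)]
            core = rng.uniform(0.1, 1.1, (2, 2, 2))
            q = np.kron(np.kron(factors[2], factors[1]), factors[0])
            vec_t = t.reshape(-1, order="F")
            vec_g = core.reshape(-1, order="F")
            expected = vec_g * (q.T @ vec_t) / (q.T @ q @ vec_g + 1e-12)
            update_core(t, core, factors)
            assert np.allclose(core.reshape(-1, order="F"), expected,
                               atol=1e-10)


class TestNonnegativeTucker:
    def test_same_seed_is_bitwise_identical(self, rng):
        x = rng.random((6, 5, 4))
        kwargs = dict(ranks=(2, 2, 2), max_iter=50, init="random",
                      random_state=11)
        a = NonnegativeTucker(**kwargs).fit(x)
        b = NonnegativeTucker(**kwargs).fit(x)
        for fa, fb in zip(a.factors_, b.factors_):
            assert np.array_equal(fa, fb)
        assert np.array_equal(a.core_, b.core_)

    def test_hosvd_init_is_deterministic(self, rng):
        x = rng.random((6, 5, 4))
        a = NonnegativeTucker(ranks=(2, 2, 2), max_iter=50).fit(x)
        b = NonnegativeTucker(ranks=(2, 2, 2), max_iter=50).fit(x)
        assert np.array_equal(a.core_, b.core_)

    def test_planted_model_recovery(self):
        t, _, _ = planted_tucker_tensor((12, 10, 15), (2, 2, 2), seed=0)
        model = NonnegativeTucker(ranks=(2, 2, 2), tol=1e-5,
                                  max_iter=20000).fit(t)
        assert model.relative_residual_ < 1e-2

    def test_overparameterized_fit_reaches_small_residual(self, rng):
        x = rng.random((4, 4, 4))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            model = NonnegativeTucker(ranks=(4, 4, 4), tol=9e-7,
                                      max_iter=120000).fit(x)
        assert model.relative_residual_ < 1e-3

    def test_nonnegativity_and_monotone_residual_trace(self, default_data):
        model = NonnegativeTucker(max_iter=100).fit(
            default_data.tensor.values)
        assert all(np.all(f >= 0) for f in model.factors_)
        assert np.all(model.core_ >= 0)
        assert np.all(model.reconstruct() >= 0)
        trace = np.asarray(model.residual_trace_)
        assert np.all(np.diff(trace) <= 1e-8 * trace[:-1] + 1e-12)

    def test_rank_warning_when_not_small(self, rng):
        with pytest.warns(UserWarning, match="ranks"):
            NonnegativeTucker(ranks=(5, 5, 5), max_iter=2).fit(
                rng.random((4, 4, 4)))

    def test_input_validation(self):
        est = NonnegativeTucker()
        with pytest.raises(ValueError):
            est.fit(np.ones((2, 2)))
        with pytest.raises(ValueError):
            est.fit(-np.ones((2, 2, 2)))

    def test_sklearn_params_roundtrip(self):
        est = NonnegativeTucker(ranks=(2, 3, 4), tol=1e-5)
        cloned = clone(est)
        assert cloned.get_params()["ranks"] == (2, 3, 4)
        cloned.set_params(max_iter=7)
        assert cloned.max_iter == 7

    def test_epsilon_absolute_stopping_mode(self):
        t, _, _ = planted_tucker_tensor((5, 5, 5), (2, 2, 2), seed=2)
        model = NonnegativeTucker(ranks=(2, 2, 2), epsilon=1e-2,
                                  max_iter=20000).fit(t)
        assert model.converged_
        assert model.residual_trace_[-1] < 1e-2
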