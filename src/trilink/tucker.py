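"""Nonnegative Tucker decomposition with multiplicative updates.

The association tensor ``T`` (n1 x n2 x n3) is approximated by
``T_hat = G x1 Z1 x2 Z2 x3 Z3`` with a small nonnegative core ``G``
(R1 x R2 x R3) and nonnegative factor matrices ``Zn`` (nn x Rn).  The
fit alternates NMF-style multiplicative updates:

* factor mode n:  ``Zn <- Zn * (T(n) Sn') / (Zn Sn Sn')`` with
  ``Sn = G(n) (kron of the other factors)'``;
* core:  ``G <- G * (T xn Zn' for all n) / (G xn Zn'Zn for all n)``,
  the tensorised form of the vectorised NMF step
  ``vec(G) <- vec(G) * (Q' vec(T)) / (Q'Q vec(G))`` with
  ``Q = Z3 (x) Z2 (x) Z1``.

Although the alternating scheme is organised like a higher-order
iteration, the updates are multiplicative and never orthogonalise the
factors; nonnegativity is preserved throughout and zero entries are
absorbing.  A small additive guard stabilises the denominators.

Unfolding convention
--------------------
``unfold(T, n)`` moves axis ``n`` first and flattens the remaining
axes in ascending order (C order).  Under this convention the identity

    unfold(G x1 Z1 x2 Z2 x3 Z3, 0) = Z1 @ unfold(G, 0) @ kron(Z2, Z3).T

holds with the Kronecker factors in ascending mode order.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "unfold", "fold", "n_mode_product", "multi_mode_product",
    "tucker_to_tensor", "update_factor", "update_core", "NonnegativeTucker",
]

#: Additive denominator guard for the multiplicative updates.
EPS_GUARD = 1e-12


def unfold(tensor: np.ndarray, mode: int) -> np.ndarray:
    """Mode-``mode`` matricisation (0-based mode)."""
    tensor = np.asarray(tensor)
    return np.moveaxis(tensor, mode, 0).reshape(tensor.shape[mode], -1)


def fold(matrix: np.ndarray, mode: int, shape: Sequence[int]) -> np.ndarray:
    """Inverse of :func:`unfold` for a tensor of the given shape."""
    shape = tuple(shape)
    rest = [s for i, s in enumerate(shape) if i != mode]
    return np.moveaxis(matrix.reshape((shape[mode], *rest)), 0, mode)


def n_mode_product(tensor: np.ndarray, matrix: np.ndarray, mode: int) -> np.ndarray:
    """Contract axis ``mode`` of ``tensor`` with the columns of ``matrix``."""
    tensor = np.asarray(tensor)
    matrix = np.asarray(matrix)
    if matrix.shape[1] != tensor.shape[mode]:
        raise ValueError(
            f"matrix has {matrix.shape[1]} columns but tensor mode {mode} "
            f"has size {tensor.shape[mode]}")
    return np.moveaxis(np.tensordot(matrix, tensor, axes=(1, mode)), 0, mode)


def multi_mode_product(tensor: np.ndarray, matrices: Sequence[np.ndarray],
                       skip: int | None = None) -> np.ndarray:
    """Apply ``n_mode_product`` along every mode (optionally skipping one)."""
    out = tensor
    for mode, matrix in enumerate(matrices):
        if mode == skip:
            continue
        out = n_mode_product(out, matrix, mode)
    return out


def tucker_to_tensor(core: np.ndarray, factors: Sequence[np.ndarray]) -> np.ndarray:
    """Reconstruction ``G x1 Z1 x2 Z2 x3 Z3``."""
    return multi_mode_product(core, factors)


def _factor_surrogate(core: np.ndarray, factors: Sequence[np.ndarray],
                      mode: int) -> np.ndarray:
    """``Sn = unfold(G applied with the other factors, mode)``."""
    return unfold(multi_mode_product(core, factors, skip=mode), mode)


def update_factor(tensor: np.ndarray, core: np.ndarray,
                  factors: list[np.ndarray], mode: int,
                  guard: float = EPS_GUARD) -> None:
    """One multiplicative update of ``factors[mode]``, in place."""
    s = _factor_surrogate(core, factors, mode)
    z = factors[mode]
    numerator = unfold(tensor, mode) @ s.T
    denominator = z @ (s @ s.T) + guard
    z *= numerator / denominator
    if not np.all(np.isfinite(z)):
        raise FloatingPointError(f"non-finite entries after mode-{mode} factor update")


def update_core(tensor: np.ndarray, core: np.ndarray,
                factors: Sequence[np.ndarray], guard: float = EPS_GUARD) -> None:
    """One multiplicative update of the core, in place (gram form)."""
    numerator = multi_mode_product(tensor, [z.T for z in factors])
    grams = [z.T @ z for z in factors]
    denominator = multi_mode_product(core, grams) + guard
    core *= numerator / denominator
    if not np.all(np.isfinite(core)):
        raise FloatingPointError("non-finite entries after core update")


def _squared_residual(tensor: np.ndarray, core: np.ndarray,
                      factors: Sequence[np.ndarray]) -> float:
    diff = tensor - tucker_to_tensor(core, factors)
    return float(np.sum(diff * diff))


class NonnegativeTucker(BaseEstimator):
    """Nonnegative Tucker model fitted by alternating multiplicative updates.

    Parameters
    ----------
    ranks : tuple of int, default (5, 5, 5)
        Core dimensions (R1, R2, R3).
    tol : float, default 1e-4
        Relative stopping threshold on the squared Frobenius residual,
        ``||T - T_hat||_F^2 / ||T||_F^2 < tol``.
    epsilon : float, optional
        If given, an *absolute* threshold ``||T - T_hat||_F^2 < epsilon``
        is used instead of ``tol``.
    max_iter : int, default 500
        Iteration cap (one iteration = factor updates for modes 1..3
        then a core update).
    guard : float, default 1e-12
        Additive denominator guard.
    init : {"hosvd", "random"}, default "hosvd"
        Initialisation.  ``"hosvd"`` takes the absolute values of the
        truncated left singular vectors of each unfolding (plus a small
        positive offset) and the matching contracted core — it is
        deterministic and spreads initial mass over every significant
        component, which matters because multiplicative updates cannot
        revive a component once its entries decay to zero: with
        ``"random"`` (uniform (0.1, 1.1)) init, data whose blocks have
        disjoint support routinely collapse onto a single block.
    random_state : int or None
        Seed for the ``"random"`` initialisation (unused by
        ``"hosvd"``, which is deterministic).  Strictly positive initial
        entries are required because zeros are absorbing under
        multiplicative updates.

    Attributes
    ----------
    core_ : ndarray of shape ``ranks``
    factors_ : list of three ndarrays, shapes (nn, Rn)
    residual_trace_ : list of float
        Squared Frobenius residual before iterating and after each
        iteration.
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, ranks: tuple[int, int, int] = (5, 5, 5),
                 tol: float = 1e-4, epsilon: float | None = None,
                 max_iter: int = 500, guard: float = EPS_GUARD,
                 init: str = "hosvd", random_state: int | None = None):
        self.ranks = ranks
        self.tol = tol
        self.epsilon = epsilon
        self.max_iter = max_iter
        self.guard = guard
        self.init = init
        self.random_state = random_state

    def _initialize(self, X: np.ndarray, ranks: tuple[int, ...]
                    ) -> tuple[np.ndarray, list[np.ndarray]]:
        if self.init == "random":
            rng = np.random.default_rng(self.random_state)
            factors = [rng.uniform(0.1, 1.1, size=(n, r))
                       for n, r in zip(X.shape, ranks)]
            core = rng.uniform(0.1, 1.1, size=ranks)
            return core, factors
        if self.init != "hosvd":
            raise ValueError(f"unknown init {self.init!r}")
        offset = 1e-2  # keep every entry strictly positive
        factors = []
        for mode, r in enumerate(ranks):
            u = np.linalg.svd(unfold(X, mode), full_matrices=False)[0]
            k = min(r, u.shape[1])
            f = np.abs(u[:, :k])
            if k < r:
                f = np.hstack([f, np.full((f.shape[0], r - k), offset)])
            factors.append(f + offset)
        core = np.abs(
            multi_mode_product(X, [f.T for f in factors])) + offset
        return core, factors

    def fit(self, X: np.ndarray, y: None = None) -> "NonnegativeTucker":
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError("expected a 3-way tensor")
        if not np.all(np.isfinite(X)) or np.any(X < 0):
            raise ValueError("tensor entries must be finite and nonnegative")
        ranks = tuple(int(r) for r in self.ranks)
        if len(ranks) != 3 or min(ranks) < 1:
            raise ValueError("ranks must be three positive integers")
        if max(ranks) > min(X.shape):
            warnings.warn(
                "requested ranks are not small relative to the tensor "
                f"dimensions (ranks={ranks}, shape={X.shape})",
                UserWarning, stacklevel=2)

        core, factors = self._initialize(X, ranks)

        norm2 = float(np.sum(X * X))
        trace = [_squared_residual(X, core, factors)]
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            for mode in range(3):
                update_factor(X, core, factors, mode, self.guard)
            update_core(X, core, factors, self.guard)
            res2 = _squared_residual(X, core, factors)
            if not np.isfinite(res2):
                raise FloatingPointError(
                    f"non-finite residual at iteration {n_iter}; trace={trace}")
            trace.append(res2)
            if self.epsilon is not None:
                converged = res2 < self.epsilon
            else:
                converged = norm2 == 0.0 or res2 / norm2 < self.tol
            if converged:
                break
        if trace[-1] > trace[0] * (1.0 + 1e-8) + 1e-12:
            raise RuntimeError(
                "residual increased over the fit; "
                f"trace head={trace[:3]}, tail={trace[-3:]}")

        self.core_ = core
        self.factors_ = factors
        self._norm2_ = norm2
        self.residual_trace_ = trace
        self.n_iter_ = n_iter
        self.converged_ = converged
        return self

    def reconstruct(self) -> np.ndarray:
        """Prediction tensor ``T* = G x1 Z1 x2 Z2 x3 Z3`` (nonnegative)."""
        check_is_fitted(self, "core_")
        return tucker_to_tensor(self.core_, self.factors_)

    @property
    def relative_residual_(self) -> float:
        """Final ``||T - T_hat||_F / ||T||_F`` (from the stored trace)."""
        check_is_fitted(self, "residual_trace_")
        if self._norm2_ == 0.0:
            return 0.0
        return float(np.sqrt(self.residual_trace_[-1] / self._norm2_))

    def fit_transform(self, X: np.ndarray, y: None = None) -> np.ndarray:
        return self.fit(X).reconstruct()
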