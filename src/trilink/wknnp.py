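"""Weighted K-nearest-neighbour profile (WKNNP) smoothing.

Sparse or all-zero interaction profiles make tensor completion
uninformative, so each axis slice of the binary association tensor is
supplemented by a weighted average of the slices of its K most similar
neighbours that carry at least one known association.  The t-th
neighbour (similarity-descending) receives weight
``w_t = alpha^(t-1) * sim_t`` while the normaliser is the plain
similarity sum ``Q = sum_t sim_t`` — note the deliberate asymmetry:
the decayed weights do not sum to ``Q`` unless ``alpha = 1``, which is
how the procedure is defined.  The three axis estimates are blended
with nonnegative fusion weights and fused into the tensor by an
elementwise maximum, so observed associations are always preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WknnpConfig:
    """Neighbour count, decay and fusion weights for profile smoothing."""

    k: int = 3
    alpha: float = 0.1
    fusion_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("K must be a positive integer")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if any(w < 0 for w in self.fusion_weights) or sum(self.fusion_weights) <= 0:
            raise ValueError("fusion weights must be nonnegative with positive sum")


def axis_knn_profile(values: np.ndarray, sim: np.ndarray, axis: int,
                     k: int = 3, alpha: float = 0.1) -> np.ndarray:
    """Neighbour-profile estimate of the tensor along one axis.

    For each entity on ``axis``: its neighbours are the ``k`` most
    similar *other* entities that have at least one known association
    (fewer if fewer are eligible), ties broken by index order.  The
    estimate is ``sum_t w_t * slice_t / Q`` with ``w_t = alpha^(t-1) *
    sim_t`` and ``Q = sum_t sim_t``.  Entities whose every eligible
    neighbour has similarity zero get a zero estimate (with a warning).
    """
    values = np.asarray(values, dtype=np.float64)
    sim = np.asarray(sim, dtype=np.float64)
    n = values.shape[axis]
    if sim.shape != (n, n):
        raise ValueError(f"similarity matrix shape {sim.shape} does not match "
                         f"axis {axis} of tensor shape {values.shape}")
    front = np.moveaxis(values, axis, 0)
    known = front.reshape(n, -1).sum(axis=1) > 0
    estimate = np.zeros_like(front)
    n_degenerate = 0
    for i in range(n):
        eligible = [j for j in range(n) if j != i and known[j]]
        if not eligible:
            n_degenerate += 1
            continue
        # similarity-descending, index-ascending on ties
        eligible.sort(key=lambda j: (-sim[i, j], j))
        chosen = eligible[:k]
        sims = sim[i, chosen]
        q = sims.sum()
        if q <= 0.0:
            n_degenerate += 1
            continue
        weights = alpha ** np.arange(len(chosen)) * sims
        estimate[i] = np.tensordot(weights, front[chosen], axes=1) / q
    if n_degenerate:
        logger.warning(
            "axis %d: %d entit%s with no usable neighbour; zero estimate kept",
            axis, n_degenerate, "y" if n_degenerate == 1 else "ies")
    return np.clip(np.moveaxis(estimate, 0, axis), 0.0, 1.0)


def fuse(values: np.ndarray, td: np.ndarray, tl: np.ndarray, tm: np.ndarray,
         fusion_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> np.ndarray:
    """Blend the three axis estimates and fuse by elementwise maximum.

    ``T_blend = (a1*T_D + a2*T_L + a3*T_M) / (a1+a2+a3)``;
    the result is ``max(T, T_blend)``, so known 1-entries survive.
    """
    a1, a2, a3 = fusion_weights
    total = a1 + a2 + a3
    if total <= 0 or min(a1, a2, a3) < 0:
        raise ValueError("fusion weights must be nonnegative with positive sum")
    blended = (a1 * td + a2 * tl + a3 * tm) / total
    return np.clip(np.maximum(values, blended), 0.0, 1.0)


def smooth_tensor(values: np.ndarray,
                  similarities: tuple[np.ndarray, np.ndarray, np.ndarray],
                  config: WknnpConfig = WknnpConfig()) -> np.ndarray:
    """Full WKNNP pass: three axis estimates, blend, fuse."""
    td = axis_knn_profile(values, similarities[0], 0, config.k, config.alpha)
    tl = axis_knn_profile(values, similarities[1], 1, config.k, config.alpha)
    tm = axis_knn_profile(values, similarities[2], 2, config.k, config.alpha)
    return fuse(values, td, tl, tm, config.fusion_weights)
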