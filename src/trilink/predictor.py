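"""End-to-end estimator: WKNNP smoothing + nonnegative Tucker completion.

``TensorLinkPredictor.fit`` takes the binary association tensor and the
three entity similarity matrices, densifies the tensor with
similarity-weighted K-nearest-neighbour profiles, fits the nonnegative
Tucker model and stores the reconstructed prediction tensor.  Candidate
(lncRNA, miRNA) pairs for a disease are ranked by their reconstructed
score, training positives excluded by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .networks import AssociationTensor
from .tucker import NonnegativeTucker
from .wknnp import WknnpConfig, smooth_tensor


class TensorLinkPredictor(BaseEstimator):
    """Score unobserved disease-(lncRNA, miRNA) triples by tensor completion.

    Parameters mirror the two pipeline stages: ``k_neighbors`` / ``alpha``
    / ``fusion_weights`` control WKNNP smoothing (disable it with
    ``smoothing=False``); ``ranks`` / ``tol`` / ``epsilon`` / ``max_iter``
    / ``random_state`` are passed to :class:`NonnegativeTucker`.

    Attributes
    ----------
    fused_tensor_ : ndarray
        The smoothed training tensor actually decomposed.
    model_ : NonnegativeTucker
        The fitted decomposition.
    prediction_ : ndarray
        The reconstructed nonnegative score tensor ``T*``.
    """

    def __init__(self, k_neighbors: int = 3, alpha: float = 0.1,
                 fusion_weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
                 smoothing: bool = True,
                 ranks: tuple[int, int, int] = (5, 5, 5), tol: float = 1e-4,
                 epsilon: float | None = None, max_iter: int = 500,
                 random_state: int | None = None):
        self.k_neighbors = k_neighbors
        self.alpha = alpha
        self.fusion_weights = fusion_weights
        self.smoothing = smoothing
        self.ranks = ranks
        self.tol = tol
        self.epsilon = epsilon
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X: np.ndarray | AssociationTensor, y: None = None, *,
            similarities: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
            ) -> "TensorLinkPredictor":
        """Fit on a binary tensor given (disease, lncRNA, miRNA) similarities."""
        if isinstance(X, AssociationTensor):
            X = X.values
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError("expected a 3-way association tensor")
        if self.smoothing:
            if similarities is None:
                raise ValueError("similarities are required when smoothing=True")
            for axis, sim in enumerate(similarities):
                if sim.shape != (X.shape[axis], X.shape[axis]):
                    raise ValueError(
                        f"similarity matrix {axis} has shape {sim.shape}, "
                        f"expected ({X.shape[axis]}, {X.shape[axis]})")
            cfg = WknnpConfig(self.k_neighbors, self.alpha,
                              tuple(self.fusion_weights))
            fused = smooth_tensor(X, similarities, cfg)
        else:
            fused = X
        model = NonnegativeTucker(
            ranks=self.ranks, tol=self.tol, epsilon=self.epsilon,
            max_iter=self.max_iter, random_state=self.random_state,
        ).fit(fused)
        self.train_tensor_ = X
        self.fused_tensor_ = fused
        self.model_ = model
        self.prediction_ = model.reconstruct()
        return self

    def predict(self, triples: np.ndarray) -> np.ndarray:
        """Scores for an (n, 3) array of (disease, lncRNA, miRNA) indices."""
        check_is_fitted(self, "prediction_")
        triples = np.asarray(triples, dtype=np.intp)
        return self.prediction_[triples[:, 0], triples[:, 1], triples[:, 2]]

    def rank_pairs(self, disease: int, exclude_known: bool = True,
                   lncrna_ids: tuple[str, ...] | None = None,
                   mirna_ids: tuple[str, ...] | None = None) -> pd.DataFrame:
        """Ranked candidate (lncRNA, miRNA) pairs for one disease."""
        check_is_fitted(self, "prediction_")
        return rank_pairs(self.prediction_, self.train_tensor_, disease,
                          exclude_known=exclude_known,
                          lncrna_ids=lncrna_ids, mirna_ids=mirna_ids)


def rank_pairs(prediction: np.ndarray, train: np.ndarray, disease: int,
               exclude_known: bool = True,
               lncrna_ids: tuple[str, ...] | None = None,
               mirna_ids: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Rank (lncRNA, miRNA) pairs for ``disease`` by predicted score.

    Scores descend; ties break by (lncRNA, miRNA) index order.  Training
    positives are flagged ``known`` and, by default, excluded from the
    candidate list.  Ranks are contiguous from 1 over the listed rows.
    """
    scores = prediction[disease]
    known = train[disease] >= 1.0
    n_l, n_m = scores.shape
    js, ks = np.unravel_index(np.arange(n_l * n_m), (n_l, n_m))
    order = np.lexsort((ks, js, -scores.ravel()))
    js, ks = js[order], ks[order]
    flat = scores.ravel()[order]
    is_known = known[js, ks]
    if exclude_known:
        keep = ~is_known
        js, ks, flat, is_known = js[keep], ks[keep], flat[keep], is_known[keep]
    table = pd.DataFrame({
        "lncRNA": [lncrna_ids[j] for j in js] if lncrna_ids else js,
        "miRNA": [mirna_ids[k] for k in ks] if mirna_ids else ks,
        "score": flat,
        "rank": np.arange(1, len(js) + 1),
        "known": is_known,
    })
    return table
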