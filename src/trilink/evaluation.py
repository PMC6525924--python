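"""Cross-validation, ROC/AUC, recall@k and parameter sweeps.

Leave-one-out protocols mask one known triple at a time, refit the
whole smoothing + decomposition pipeline on the masked tensor and rank
the held-out triple against the unobserved candidate set — globally
(all zero entries of the training tensor) or locally (zero entries of
the same disease only).  Because scores from different refits are not
directly comparable, each held-out triple contributes its *normalised
rank* among its candidate negatives (midrank on ties); the pooled AUC
is the mean normalised rank and the ROC curve is its exceedance curve.

k-fold cross-validation masks one fold of known triples at a time; the
held-out positives of a fold are scored against the negatives of the
same fit, so a conventional label/score AUC applies per fold.  The
partition is repeated with fresh seeds and the mean +/- sd over
repeat-level means is reported.

Similarities during cross-validation are supplied either as a frozen
triple of matrices ("fast" mode) or as a callable receiving the masked
tensor and returning the triple ("strict" mode), so that any
association-derived similarity component can be recomputed without the
held-out label.  WKNNP smoothing is always recomputed per mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .predictor import TensorLinkPredictor

logger = logging.getLogger(__name__)

SimTriple = tuple[np.ndarray, np.ndarray, np.ndarray]
SimilaritySource = SimTriple | Callable[[np.ndarray], SimTriple]


@dataclass
class RocCurve:
    """ROC points and trapezoidal area."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class LoocvResult:
    """Pooled leave-one-out outcome with per-positive ranks."""

    curve: RocCurve
    #: rows (disease, lncRNA, miRNA, normalized_rank, rank, n_candidates)
    ranks: pd.DataFrame

    @property
    def auc(self) -> float:
        return self.curve.auc


@dataclass
class LocalLoocvResult:
    """Per-disease pooled curves plus their mean AUC."""

    per_disease: dict[int, RocCurve]
    ranks: pd.DataFrame
    mean_auc: float


@dataclass
class KfoldResult:
    mean_auc: float
    sd_auc: float
    repeat_aucs: np.ndarray
    fold_aucs: np.ndarray


def auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Trapezoidal ROC area with midrank tie handling."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.min() == labels.max():
        raise ValueError("AUC needs at least one positive and one negative")
    return float(roc_auc_score(labels, scores))


def recall_at_k(ranks: Sequence[float], k_grid: Sequence[int]) -> np.ndarray:
    """Fraction of held-out positives ranked within the top k, per k."""
    ranks = np.asarray(ranks, dtype=np.float64)
    if ranks.size == 0:
        raise ValueError("no held-out positives")
    return np.asarray([(ranks <= k).mean() for k in k_grid])


def _normalized_rank(score: float, negatives: np.ndarray) -> tuple[float, float]:
    """(fraction of negatives below, 1-based midrank) for one positive."""
    below = float(np.count_nonzero(negatives < score))
    ties = float(np.count_nonzero(negatives == score))
    u = (below + 0.5 * ties) / negatives.size
    rank = negatives.size - below - 0.5 * ties + 1.0
    return u, rank


def _roc_from_normalized_ranks(u: np.ndarray) -> RocCurve:
    """Exceedance curve of per-positive normalised ranks; AUC = mean(u)."""
    miss = np.sort(1.0 - u)  # per positive: fraction of negatives above it
    fpr = np.concatenate(([0.0], np.unique(miss), [1.0]))
    tpr = np.asarray([(miss <= f).mean() for f in fpr])
    return RocCurve(fpr=fpr, tpr=tpr, auc=float(u.mean()))


def _resolve_similarities(source: SimilaritySource | None,
                          tensor: np.ndarray) -> SimTriple | None:
    if callable(source):
        return source(tensor)
    return source


def _fit_prediction(tensor: np.ndarray, source: SimilaritySource | None,
                    params: Mapping | None, seed: int | None) -> np.ndarray:
    params = dict(params or {})
    params.setdefault("random_state", seed)
    sims = _resolve_similarities(source, tensor)
    if sims is None:
        params["smoothing"] = False
    est = TensorLinkPredictor(**params)
    est.fit(tensor, similarities=sims)
    return est.prediction_


def _loocv_rows(tensor: np.ndarray, similarities: SimilaritySource | None,
                predictor_params: Mapping | None, seed: int,
                local: bool) -> pd.DataFrame:
    tensor = np.asarray(tensor, dtype=np.float64)
    positives = np.argwhere(tensor >= 1.0)
    if len(positives) < 2:
        raise ValueError("leave-one-out needs at least 2 known triples")
    base_negative = tensor < 1.0
    rows = []
    for i, j, k in positives:
        masked = tensor.copy()
        masked[i, j, k] = 0.0
        prediction = _fit_prediction(masked, similarities, predictor_params, seed)
        if local:
            neg_mask = base_negative[i].copy()
            neg_mask[j, k] = False
            negatives = prediction[i][neg_mask]
        else:
            neg_mask = base_negative.copy()
            neg_mask[i, j, k] = False
            negatives = prediction[neg_mask]
        if negatives.size == 0:
            logger.warning("triple (%d,%d,%d): no candidate negatives; skipped",
                           i, j, k)
            continue
        u, rank = _normalized_rank(float(prediction[i, j, k]), negatives)
        rows.append((int(i), int(j), int(k), u, rank, int(negatives.size)))
    return pd.DataFrame(rows, columns=["disease", "lncRNA", "miRNA",
                                       "normalized_rank", "rank", "n_candidates"])


def global_loocv(tensor: np.ndarray,
                 similarities: SimilaritySource | None = None,
                 predictor_params: Mapping | None = None,
                 seed: int = 0) -> LoocvResult:
    """Global leave-one-out: each held-out triple vs all unobserved triples."""
    ranks = _loocv_rows(tensor, similarities, predictor_params, seed, local=False)
    curve = _roc_from_normalized_ranks(ranks["normalized_rank"].to_numpy())
    return LoocvResult(curve=curve, ranks=ranks)


def local_loocv(tensor: np.ndarray,
                similarities: SimilaritySource | None = None,
                predictor_params: Mapping | None = None,
                seed: int = 0) -> LocalLoocvResult:
    """Local leave-one-out: candidates restricted to the same disease."""
    ranks = _loocv_rows(tensor, similarities, predictor_params, seed, local=True)
    per_disease: dict[int, RocCurve] = {}
    for d, grp in ranks.groupby("disease"):
        per_disease[int(d)] = _roc_from_normalized_ranks(
            grp["normalized_rank"].to_numpy())
    mean_auc = float(np.mean([c.auc for c in per_disease.values()]))
    return LocalLoocvResult(per_disease=per_disease, ranks=ranks,
                            mean_auc=mean_auc)


def _partition(positives: np.ndarray, folds: int, rng: np.random.Generator,
               stratify: bool) -> list[np.ndarray]:
    """Fold assignment over positive triples, optionally disease-stratified."""
    assign = np.empty(len(positives), dtype=np.intp)
    if stratify:
        offset = 0
        for d in np.unique(positives[:, 0]):
            idx = np.nonzero(positives[:, 0] == d)[0]
            rng.shuffle(idx)
            assign[idx] = (np.arange(len(idx)) + offset) % folds
            offset += len(idx)
    else:
        perm = rng.permutation(len(positives))
        assign[perm] = np.arange(len(positives)) % folds
    return [np.nonzero(assign == f)[0] for f in range(folds)]


def kfold_cv(tensor: np.ndarray,
             similarities: SimilaritySource | None = None,
             folds: int = 10, repeats: int = 10, seed: int = 0,
             stratify: bool = True,
             predictor_params: Mapping | None = None) -> KfoldResult:
    """Repeated k-fold CV over known triples; mean +/- sd of AUC."""
    tensor = np.asarray(tensor, dtype=np.float64)
    if folds < 2:
        raise ValueError("k-fold needs folds >= 2")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    positives = np.argwhere(tensor >= 1.0)
    if len(positives) < folds:
        raise ValueError("fewer known triples than folds")
    base_negative = tensor < 1.0
    repeat_aucs = []
    fold_aucs = []
    for r in range(repeats):
        rng = np.random.default_rng((seed, r))
        this_repeat = []
        for fold_idx in _partition(positives, folds, rng, stratify):
            if fold_idx.size == 0:
                continue
            masked = tensor.copy()
            held = positives[fold_idx]
            masked[held[:, 0], held[:, 1], held[:, 2]] = 0.0
            prediction = _fit_prediction(masked, similarities,
                                         predictor_params, seed)
            pos_scores = prediction[held[:, 0], held[:, 1], held[:, 2]]
            neg_scores = prediction[base_negative]
            labels = np.concatenate([np.ones(pos_scores.size),
                                     np.zeros(neg_scores.size)])
            this_repeat.append(auc(labels,
                                   np.concatenate([pos_scores, neg_scores])))
        fold_aucs.extend(this_repeat)
        repeat_aucs.append(float(np.mean(this_repeat)))
    repeat_aucs = np.asarray(repeat_aucs)
    return KfoldResult(
        mean_auc=float(repeat_aucs.mean()),
        sd_auc=float(repeat_aucs.std(ddof=1)) if repeats > 1 else 0.0,
        repeat_aucs=repeat_aucs,
        fold_aucs=np.asarray(fold_aucs),
    )


def permuted_score_auc(tensor: np.ndarray, seed: int = 0) -> float:
    """Label-free null: score triples with a seeded random tensor (~0.5)."""
    tensor = np.asarray(tensor, dtype=np.float64)
    rng = np.random.default_rng(seed)
    scores = rng.random(tensor.shape)
    positives = np.argwhere(tensor >= 1.0)
    base_negative = tensor < 1.0
    us = []
    for i, j, k in positives:
        neg_mask = base_negative.copy()
        negatives = scores[neg_mask]
        u, _ = _normalized_rank(float(scores[i, j, k]), negatives)
        us.append(u)
    return float(np.mean(us))


def parameter_sweep(tensor: np.ndarray,
                    similarities: SimilaritySource | None = None,
                    k_values: Sequence[int] = (3,),
                    alpha_values: Sequence[float] = (0.1,),
                    scheme: str = "global-loocv",
                    seed: int = 0, folds: int = 10, repeats: int = 1,
                    predictor_params: Mapping | None = None) -> pd.DataFrame:
    """One AUC per (K, alpha) grid point under a fixed scheme and seed."""
    rows = []
    for k in k_values:
        for a in alpha_values:
            params = dict(predictor_params or {})
            params["k_neighbors"] = int(k)
            params["alpha"] = float(a)
            if scheme == "global-loocv":
                value = global_loocv(tensor, similarities, params, seed).auc
            elif scheme == "local-loocv":
                value = local_loocv(tensor, similarities, params, seed).mean_auc
            elif scheme == "kfold":
                value = kfold_cv(tensor, similarities, folds=folds,
                                 repeats=repeats, seed=seed,
                                 predictor_params=params).mean_auc
            else:
                raise ValueError(f"unknown scheme {scheme!r}")
            rows.append((int(k), float(a), float(value)))
    return pd.DataFrame(rows, columns=["K", "alpha", "auc"])
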