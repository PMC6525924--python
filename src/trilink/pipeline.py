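"""Wiring from edge-list files to tensor, similarities and predictions.

The similarity stage follows the construction used for the real
association data: disease similarity averages MeSH semantic similarity
(where available) with the mean of the two disease GIP kernels computed
from the disease x lncRNA and disease x miRNA adjacency profiles;
lncRNA and miRNA similarities average a best-match functional
similarity (over associated-disease sets) with the GIP kernel on their
own association profiles.

For cross-validation two similarity sources are offered: the frozen
matrices ("fast"), or a strict provider that recomputes the GIP
components from the masked tensor's unfoldings on every refit while
keeping the semantic/functional components frozen — masking a single
triple does not delete the underlying pairwise database associations,
which is why only the tensor-derived component is refit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from .networks import (AssociationTensor, TripartiteNetwork,
                       build_tensor_from_edge_lists, load_edge_list)
from .similarity import (MeshDag, SimilarityMatrix, combine_disease_gip,
                         combine_similarity, disease_semantic_similarity,
                         functional_similarity, gip_similarity,
                         semantic_scores_for)
from .tucker import unfold

SimTriple = tuple[np.ndarray, np.ndarray, np.ndarray]


@dataclass
class SimilarityBundle:
    """All similarity products for one dataset, plus intermediates."""

    disease: SimilarityMatrix      # combined disSim
    lncrna: SimilarityMatrix       # combined lncSim
    mirna: SimilarityMatrix        # combined miRSim
    disease_semantic: np.ndarray
    disease_gip: np.ndarray
    lncrna_functional: np.ndarray
    lncrna_gip: np.ndarray
    mirna_functional: np.ndarray
    mirna_gip: np.ndarray
    semantic_mask: np.ndarray

    @property
    def matrices(self) -> SimTriple:
        return (self.disease.values, self.lncrna.values, self.mirna.values)


def build_from_files(dl_path: str | Path, dm_path: str | Path,
                     lm_path: str | Path
                     ) -> tuple[AssociationTensor, TripartiteNetwork]:
    """Load the three edge lists and build tensor + tripartite network."""
    dl = load_edge_list(dl_path, ("disease", "lncRNA"))
    dm = load_edge_list(dm_path, ("disease", "miRNA"))
    lm = load_edge_list(lm_path, ("lncRNA", "miRNA"))
    return build_tensor_from_edge_lists(dl, dm, lm)


def compute_similarities(tri: TripartiteNetwork,
                         mesh: MeshDag | None = None,
                         decay: float = 0.5) -> SimilarityBundle:
    """Similarity matrices over the retained tensor axes."""
    y_dl = tri.y_dl.astype(np.float64)
    y_dm = tri.y_dm.astype(np.float64)

    if mesh is not None:
        scores, mask = semantic_scores_for(mesh, tri.disease_ids, decay)
        sem = disease_semantic_similarity(scores)
    else:
        # no vocabulary: semantic part degenerates to identity, GIP carries all
        sem = np.eye(len(tri.disease_ids))
        mask = np.zeros(len(tri.disease_ids), dtype=bool)

    gip_ld = gip_similarity(y_dl)
    gip_md = gip_similarity(y_dm)
    gip_d = combine_disease_gip(gip_ld, gip_md)
    dis_sim = combine_similarity(sem, gip_d, semantic_mask=mask)

    lnc_fun = functional_similarity(y_dl.T, sem)
    lnc_gip = gip_similarity(y_dl.T)
    lnc_sim = combine_similarity(lnc_fun, lnc_gip)

    mir_fun = functional_similarity(y_dm.T, sem)
    mir_gip = gip_similarity(y_dm.T)
    mir_sim = combine_similarity(mir_fun, mir_gip)

    return SimilarityBundle(
        disease=SimilarityMatrix("disSim", dis_sim, tri.disease_ids),
        lncrna=SimilarityMatrix("lncSim", lnc_sim, tri.lncrna_ids),
        mirna=SimilarityMatrix("miRSim", mir_sim, tri.mirna_ids),
        disease_semantic=sem,
        disease_gip=gip_d,
        lncrna_functional=lnc_fun,
        lncrna_gip=lnc_gip,
        mirna_functional=mir_fun,
        mirna_gip=mir_gip,
        semantic_mask=mask,
    )


def strict_similarity_provider(bundle: SimilarityBundle
                               ) -> Callable[[np.ndarray], SimTriple]:
    """CV similarity source refitting the GIP parts per masked tensor.

    The semantic (disease) and functional (lncRNA/miRNA) components are
    frozen from ``bundle``; the GIP kernels are recomputed from the rows
    of the masked tensor's three unfoldings, so the held-out association
    cannot leak through a tensor-derived kernel.
    """
    sem = bundle.disease_semantic
    mask = bundle.semantic_mask
    lnc_fun = bundle.lncrna_functional
    mir_fun = bundle.mirna_functional

    def provider(masked: np.ndarray) -> SimTriple:
        d_gip = gip_similarity(unfold(masked, 0))
        l_gip = gip_similarity(unfold(masked, 1))
        m_gip = gip_similarity(unfold(masked, 2))
        return (
            combine_similarity(sem, d_gip, semantic_mask=mask),
            combine_similarity(lnc_fun, l_gip),
            combine_similarity(mir_fun, m_gip),
        )

    return provider


def similarity_source(bundle: SimilarityBundle, mode: str = "strict"):
    """``'strict'`` -> per-mask provider; ``'fast'`` -> frozen matrices."""
    if mode == "strict":
        return strict_similarity_provider(bundle)
    if mode == "fast":
        return bundle.matrices
    raise ValueError(f"unknown similarity mode {mode!r}")
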