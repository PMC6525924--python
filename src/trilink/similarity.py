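"""Entity similarity matrices.

Disease similarity combines two sources:

* **Semantic similarity** from the MeSH disease hierarchy.  Each disease
  term spans a directed acyclic graph of itself and its ancestors
  (derived from MeSH tree-number prefixes).  An ancestor ``a``
  contributes ``D_d(a) = max(delta * D_d(c))`` over its children ``c``
  on paths toward ``d`` (``D_d(d) = 1``), with decay ``delta = 0.5``.
  Two diseases are similar in proportion to the contributions of their
  shared ancestors, normalised by their total semantic values ``DV``.

* **Gaussian interaction-profile (GIP) kernel similarity** from binary
  association profiles: ``exp(-gamma * ||p_i - p_j||^2)`` with the
  bandwidth ``gamma = n / sum_i ||p_i||^2`` set by the mean squared
  profile norm.

lncRNA and miRNA similarity combine a best-match-average functional
similarity (over each entity's associated-disease sets, scored by the
disease semantic matrix) with the GIP kernel on their association
profiles.  All combined matrices are elementwise means, clipped to
[0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

#: Default semantic-contribution decay factor.
DEFAULT_DECAY = 0.5


@dataclass
class SimilarityMatrix:
    """A named, symmetric [0, 1] similarity matrix over one entity axis."""

    kind: str
    values: np.ndarray
    ids: tuple[str, ...]
    bandwidth: float | None = None


class MeshDag:
    """MeSH descriptor vocabulary: tree numbers and per-term ancestor DAGs.

    Built from the ASCII descriptor format (``*NEWRECORD`` blocks with
    ``MH = `` heading and ``MN = `` tree-number lines).  A term's DAG
    contains the term itself plus every ancestor term reachable by
    truncating its tree numbers one dot-level at a time; edges run
    parent -> child.
    """

    def __init__(self, term_trees: Mapping[str, tuple[str, ...]]):
        self.term_trees: dict[str, tuple[str, ...]] = dict(term_trees)
        self.tree_to_term: dict[str, str] = {}
        for term, trees in self.term_trees.items():
            for tn in trees:
                self.tree_to_term[tn] = term

    def __contains__(self, term: str) -> bool:
        return term in self.term_trees

    def dag(self, term: str) -> nx.DiGraph:
        """Ancestor DAG of ``term``; empty (flagged) if absent from MeSH."""
        g = nx.DiGraph()
        if term not in self.term_trees:
            logger.warning("disease %r absent from MeSH descriptors", term)
            return g
        g.add_node(term)
        for tn in self.term_trees[term]:
            parts = tn.split(".")
            chain = [".".join(parts[: i + 1]) for i in range(len(parts))]
            prev_term: str | None = None
            for prefix in chain:
                t = self.tree_to_term.get(prefix)
                if t is None:
                    continue
                g.add_node(t)
                if prev_term is not None and prev_term != t:
                    g.add_edge(prev_term, t)
                prev_term = t
        return g


def parse_mesh(source: str | Path | IO[str]) -> MeshDag:
    """Parse an ASCII MeSH descriptor file into a :class:`MeshDag`."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text(encoding="utf-8").splitlines()
    term_trees: dict[str, list[str]] = {}
    heading: str | None = None
    trees: list[str] = []

    def flush() -> None:
        nonlocal heading, trees
        if trees and heading is None:
            raise ValueError("MeSH record has tree numbers but no MH heading")
        if heading is not None:
            term_trees.setdefault(heading, []).extend(trees)
        heading, trees = None, []

    for line in lines:
        line = line.strip()
        if line == "*NEWRECORD":
            flush()
        elif line.startswith("MH = "):
            heading = line[5:].strip()
        elif line.startswith("MN = "):
            trees.append(line[5:].strip())
    flush()
    return MeshDag({t: tuple(v) for t, v in term_trees.items()})


@dataclass
class SemanticScores:
    """Decayed ancestor contributions ``D_d`` and their sum ``DV(d)``."""

    disease: str
    contribution: dict[str, float]
    decay: float = DEFAULT_DECAY
    total: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = float(sum(self.contribution.values()))


def semantic_contribution(dag: nx.DiGraph, disease: str,
                          decay: float = DEFAULT_DECAY) -> SemanticScores:
    """Bottom-up decayed contribution of every ancestor in ``dag``.

    ``D_d(d) = 1``; for an ancestor ``a``, ``D_d(a)`` is ``decay`` times
    the largest contribution among its children on paths toward ``d``.
    An empty DAG (disease missing from MeSH) yields the trivial scores
    ``{d: 1}``, ``DV = 1``.
    """
    if not 0.0 < decay < 1.0:
        raise ValueError("decay must lie in (0, 1)")
    if dag.number_of_nodes() == 0 or disease not in dag:
        return SemanticScores(disease, {disease: 1.0}, decay)
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("cycle detected in disease DAG")
    contribution: dict[str, float] = {disease: 1.0}
    # edges run parent -> child; a node's score depends on its children,
    # so walk the topological order back to front
    for node in reversed(list(nx.topological_sort(dag))):
        if node in contribution:
            continue
        child_scores = [contribution[c] for c in dag.successors(node)
                        if c in contribution]
        if child_scores:  # nodes with no path to `disease` carry no score
            contribution[node] = decay * max(child_scores)
    return SemanticScores(disease, contribution, decay)


def disease_semantic_similarity(
    scores: Sequence[SemanticScores],
) -> np.ndarray:
    """Pairwise semantic similarity from shared-ancestor contributions."""
    n = len(scores)
    sim = np.zeros((n, n))
    for i in range(n):
        ci = scores[i].contribution
        for j in range(i, n):
            cj = scores[j].contribution
            shared = ci.keys() & cj.keys()
            if shared:
                num = sum(ci[t] + cj[t] for t in shared)
                sim[i, j] = sim[j, i] = num / (scores[i].total + scores[j].total)
    return np.clip(sim, 0.0, 1.0)


def gip_bandwidth(profiles: np.ndarray) -> float:
    """Kernel bandwidth: profile count over the summed squared norms."""
    profiles = np.asarray(profiles, dtype=np.float64)
    total = float(np.sum(profiles * profiles))
    if total == 0.0:
        raise ValueError("all interaction profiles are zero; GIP bandwidth undefined")
    return profiles.shape[0] / total


def gip_similarity(profiles: np.ndarray) -> np.ndarray:
    """Gaussian interaction-profile kernel over the rows of ``profiles``."""
    profiles = np.asarray(profiles, dtype=np.float64)
    gamma = gip_bandwidth(profiles)
    norms2 = np.sum(profiles * profiles, axis=1)
    sq = norms2[:, None] + norms2[None, :] - 2.0 * profiles @ profiles.T
    np.clip(sq, 0.0, None, out=sq)
    sim = np.exp(-gamma * sq)
    np.fill_diagonal(sim, 1.0)
    return np.clip(sim, 0.0, 1.0)


def combine_disease_gip(gip_ld: np.ndarray, gip_md: np.ndarray) -> np.ndarray:
    """Mean of the two disease GIP kernels (lncRNA- and miRNA-profile based)."""
    if gip_ld.shape != gip_md.shape:
        raise ValueError("disease GIP matrices must share one disease index")
    return np.clip((gip_ld + gip_md) / 2.0, 0.0, 1.0)


def functional_similarity(assoc: np.ndarray, disease_sim: np.ndarray) -> np.ndarray:
    """Best-match-average functional similarity.

    ``assoc`` is an entity x disease binary matrix; each entity is
    represented by its associated-disease set, and a pair is scored by
    the mean of best-match disease similarities across both sets.
    Entities with no associated disease get similarity 0 (with a
    warning); ``sim(i, i) = 1`` otherwise.
    """
    assoc = np.asarray(assoc)
    n = assoc.shape[0]
    if assoc.shape[1] != disease_sim.shape[0]:
        raise ValueError("association matrix and disease similarity disagree "
                         "on the number of diseases")
    sets = [np.nonzero(assoc[i])[0] for i in range(n)]
    n_empty = sum(1 for s in sets if s.size == 0)
    if n_empty:
        logger.warning(
            "%d entit%s with no associated disease; functional similarity 0",
            n_empty, "y" if n_empty == 1 else "ies")
    sim = np.zeros((n, n))
    for i in range(n):
        di = sets[i]
        if di.size == 0:
            continue
        for j in range(i, n):
            dj = sets[j]
            if dj.size == 0:
                continue
            block = disease_sim[np.ix_(di, dj)]
            best = block.max(axis=1).sum() + block.max(axis=0).sum()
            sim[i, j] = sim[j, i] = best / (di.size + dj.size)
    return np.clip(sim, 0.0, 1.0)


def combine_similarity(fun: np.ndarray, gip: np.ndarray,
                       semantic_mask: np.ndarray | None = None) -> np.ndarray:
    """Elementwise mean of a functional/semantic and a GIP matrix.

    When ``semantic_mask`` is given (disease axis), entries involving a
    disease without MeSH semantics fall back to the GIP value alone.
    """
    if fun.shape != gip.shape:
        raise ValueError("similarity matrices must have identical shapes")
    combined = (fun + gip) / 2.0
    if semantic_mask is not None:
        mask = np.asarray(semantic_mask, dtype=bool)
        both = np.outer(mask, mask)
        combined = np.where(both, combined, gip)
    return np.clip(combined, 0.0, 1.0)


def semantic_scores_for(mesh: MeshDag, diseases: Iterable[str],
                        decay: float = DEFAULT_DECAY
                        ) -> tuple[list[SemanticScores], np.ndarray]:
    """Scores for each disease plus a boolean found-in-MeSH mask."""
    scores: list[SemanticScores] = []
    mask: list[bool] = []
    for d in diseases:
        scores.append(semantic_contribution(mesh.dag(d), d, decay))
        mask.append(d in mesh)
    return scores, np.asarray(mask, dtype=bool)
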