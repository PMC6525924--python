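"""Association networks and the disease x lncRNA x miRNA tensor.

Three bipartite association networks (disease-lncRNA, disease-miRNA,
lncRNA-miRNA) are read from tab-separated edge lists.  A triple
(d, l, m) enters the tripartite network exactly when its three projected
pairs are edges of the respective bipartite networks, i.e. when the
triple closes a triangle across the three networks.  Entities that take
part in no triangle are dropped.  The retained triples define a binary
3-way association tensor ``T`` with axes (disease, lncRNA, miRNA).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

logger = logging.getLogger(__name__)

#: Recognised entity kinds, in tensor axis order.
ENTITY_KINDS = ("disease", "lncRNA", "miRNA")


@dataclass(frozen=True)
class EdgeList:
    """A deduplicated list of (source, target) association pairs.

    ``kinds`` names the entity kind of each column and must be two
    distinct members of :data:`ENTITY_KINDS`.
    """

    pairs: tuple[tuple[str, str], ...]
    kinds: tuple[str, str]

    def __post_init__(self) -> None:
        a, b = self.kinds
        if a not in ENTITY_KINDS or b not in ENTITY_KINDS:
            raise ValueError(f"unknown entity kind in {self.kinds!r}")
        if a == b:
            raise ValueError("edge list endpoints must have distinct kinds")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class BipartiteNetwork:
    """Binary bipartite adjacency with ordered id -> index maps."""

    left_index: dict[str, int]
    right_index: dict[str, int]
    adjacency: np.ndarray  # shape (n_left, n_right), entries in {0, 1}
    kinds: tuple[str, str]

    @property
    def left_ids(self) -> tuple[str, ...]:
        return tuple(self.left_index)

    @property
    def right_ids(self) -> tuple[str, ...]:
        return tuple(self.right_index)


@dataclass
class TripartiteNetwork:
    """Triangle closure of three coupled bipartite networks.

    ``triples`` holds (i, j, k) index triples into the retained
    disease / lncRNA / miRNA id lists.  The aligned adjacency matrices
    ``y_dl``, ``y_dm``, ``y_lm`` are restricted to the retained
    entities and are the interaction-profile sources for the Gaussian
    kernel similarities.
    """

    disease_ids: tuple[str, ...]
    lncrna_ids: tuple[str, ...]
    mirna_ids: tuple[str, ...]
    triples: frozenset[tuple[int, int, int]]
    y_dl: np.ndarray = field(repr=False)
    y_dm: np.ndarray = field(repr=False)
    y_lm: np.ndarray = field(repr=False)

    @property
    def retained_diseases(self) -> frozenset[str]:
        return frozenset(self.disease_ids)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.disease_ids), len(self.lncrna_ids), len(self.mirna_ids))


@dataclass
class AssociationTensor:
    """Binary (or, after smoothing, [0, 1]-valued) 3-way association array."""

    values: np.ndarray
    disease_ids: tuple[str, ...]
    lncrna_ids: tuple[str, ...]
    mirna_ids: tuple[str, ...]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def n_associations(self) -> int:
        return int(np.count_nonzero(self.values))

    def index_of(self, disease: str) -> int:
        return self.disease_ids.index(disease)


def load_edge_list(path: str | Path, kinds: tuple[str, str]) -> EdgeList:
    """Read a tab-separated edge list; ``#`` starts a comment line.

    Pairs are deduplicated in file order; identifier whitespace is
    trimmed, case preserved.  Raises on missing files, lines with fewer
    than two fields (reporting the line number) and empty results.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"edge list not found: {path}")
    pairs: dict[tuple[str, str], None] = {}
    n_dup = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(
                    f"{path}:{lineno}: expected two tab-separated identifiers, "
                    f"got {line!r}"
                )
            pair = (fields[0], fields[1])
            if pair in pairs:
                n_dup += 1
            pairs[pair] = None
    if not pairs:
        raise ValueError(f"{path}: no associations found")
    if n_dup:
        logger.warning("%s: dropped %d duplicate association(s)", path, n_dup)
    return EdgeList(pairs=tuple(pairs), kinds=kinds)


def build_bipartite(edges: EdgeList) -> BipartiteNetwork:
    """Materialize a binary adjacency from an edge list.

    Index maps are ordered by first appearance in the edge list.
    """
    left_index: dict[str, int] = {}
    right_index: dict[str, int] = {}
    for s, t in edges.pairs:
        left_index.setdefault(s, len(left_index))
        right_index.setdefault(t, len(right_index))
    adj = np.zeros((len(left_index), len(right_index)), dtype=np.int8)
    for s, t in edges.pairs:
        adj[left_index[s], right_index[t]] = 1
    return BipartiteNetwork(left_index, right_index, adj, edges.kinds)


def _union_index(*id_sequences: Iterable[str]) -> dict[str, int]:
    index: dict[str, int] = {}
    for seq in id_sequences:
        for name in seq:
            index.setdefault(name, len(index))
    return index


def _aligned(net: BipartiteNetwork, rows: dict[str, int], cols: dict[str, int],
             transpose: bool = False) -> np.ndarray:
    """Embed a bipartite adjacency into union row/column index maps."""
    adj = net.adjacency.T if transpose else net.adjacency
    row_ids = net.right_ids if transpose else net.left_ids
    col_ids = net.left_ids if transpose else net.right_ids
    out = np.zeros((len(rows), len(cols)), dtype=np.int8)
    r = np.fromiter((rows[i] for i in row_ids), dtype=np.intp, count=len(row_ids))
    c = np.fromiter((cols[j] for j in col_ids), dtype=np.intp, count=len(col_ids))
    out[np.ix_(r, c)] = adj
    return out


def build_tripartite(g1: BipartiteNetwork, g2: BipartiteNetwork,
                     g3: BipartiteNetwork) -> TripartiteNetwork:
    """Exhaustive triangle enumeration over three coupled networks.

    ``g1`` must be disease x lncRNA, ``g2`` disease x miRNA and ``g3``
    lncRNA x miRNA.  A triple (d, l, m) is retained iff all three of
    its projected pairs are edges; entities without any triangle are
    dropped from the index maps.  The enumeration is order-independent,
    so the result is deterministic for a given input.
    """
    expect = [("disease", "lncRNA"), ("disease", "miRNA"), ("lncRNA", "miRNA")]
    for net, kinds in zip((g1, g2, g3), expect):
        if net.kinds != kinds:
            raise ValueError(f"expected a {kinds[0]} x {kinds[1]} network, "
                             f"got {net.kinds[0]} x {net.kinds[1]}")

    d_index = _union_index(g1.left_ids, g2.left_ids)
    l_index = _union_index(g1.right_ids, g3.left_ids)
    m_index = _union_index(g2.right_ids, g3.right_ids)

    a_dl = _aligned(g1, d_index, l_index).astype(bool)
    a_dm = _aligned(g2, d_index, m_index).astype(bool)
    a_lm = _aligned(g3, l_index, m_index).astype(bool)

    triples: list[tuple[int, int, int]] = []
    for i in range(len(d_index)):
        # candidate (l, m) pairs for disease i: outer product of its two
        # association profiles, intersected with the lncRNA-miRNA edges
        mask = np.logical_and(np.outer(a_dl[i], a_dm[i]), a_lm)
        js, ks = np.nonzero(mask)
        triples.extend((i, int(j), int(k)) for j, k in zip(js, ks))

    keep_d = sorted({t[0] for t in triples})
    keep_l = sorted({t[1] for t in triples})
    keep_m = sorted({t[2] for t in triples})
    remap_d = {old: new for new, old in enumerate(keep_d)}
    remap_l = {old: new for new, old in enumerate(keep_l)}
    remap_m = {old: new for new, old in enumerate(keep_m)}

    d_ids = tuple(list(d_index)[i] for i in keep_d)
    l_ids = tuple(list(l_index)[j] for j in keep_l)
    m_ids = tuple(list(m_index)[k] for k in keep_m)

    net = TripartiteNetwork(
        disease_ids=d_ids,
        lncrna_ids=l_ids,
        mirna_ids=m_ids,
        triples=frozenset(
            (remap_d[i], remap_l[j], remap_m[k]) for i, j, k in triples
        ),
        y_dl=a_dl[np.ix_(keep_d, keep_l)].astype(np.int8),
        y_dm=a_dm[np.ix_(keep_d, keep_m)].astype(np.int8),
        y_lm=a_lm[np.ix_(keep_l, keep_m)].astype(np.int8),
    )
    logger.info(
        "tripartite network: %d diseases, %d lncRNAs, %d miRNAs, %d triples",
        *net.shape, len(net.triples),
    )
    return net


def build_tensor(net: TripartiteNetwork) -> AssociationTensor:
    """Binary tensor T with T[i, j, k] = 1 iff (i, j, k) is a retained triple."""
    values = np.zeros(net.shape, dtype=np.float64)
    for i, j, k in net.triples:
        values[i, j, k] = 1.0
    return AssociationTensor(values, net.disease_ids, net.lncrna_ids, net.mirna_ids)


def build_tensor_from_edge_lists(
    dl: EdgeList, dm: EdgeList, lm: EdgeList
) -> tuple[AssociationTensor, TripartiteNetwork]:
    """Convenience: edge lists -> tripartite network -> tensor."""
    tri = build_tripartite(build_bipartite(dl), build_bipartite(dm),
                           build_bipartite(lm))
    return build_tensor(tri), tri
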