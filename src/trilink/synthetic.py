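"""Seeded synthetic datasets with planted block structure.

The generator emulates the statistical structure the prediction model
assumes: functionally related entities share disease associations, so
the association tensor is approximately low multilinear rank.  Entities
of each kind are split into latent blocks; bipartite edges appear with
high probability within a block and low probability across blocks, and
independent flip noise corrupts every edge indicator.  Triangles of the
noiseless networks are the ground-truth triples; triangles lost to
noise become held-out "future" associations for recovery tests.  A toy
MeSH-like descriptor file groups same-block diseases under a shared
ancestor term, so semantic similarity correlates with block identity.

Defaults (12 diseases x 10 lncRNAs x 15 miRNAs, 2 blocks, within-block
edge probability 0.85, cross-block 0.05, 5% flip noise) give a
nondegenerate but seconds-scale benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .networks import EdgeList

__all__ = ["FixtureSpec", "SyntheticDataset", "generate", "write_dataset",
           "planted_tucker_tensor"]


@dataclass(frozen=True)
class FixtureSpec:
    """Size, block structure, noise and seed of a synthetic dataset."""

    seed: int
    n_diseases: int = 12
    n_lncrnas: int = 10
    n_mirnas: int = 15
    n_blocks: int = 2
    p_within: float = 0.85
    p_between: float = 0.05
    edge_noise: float = 0.05
    dag_depth: int = 2

    def __post_init__(self) -> None:
        for p in (self.p_within, self.p_between, self.edge_noise):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_blocks < 1:
            raise ValueError("need at least one block")
        if self.n_blocks > min(self.n_diseases, self.n_lncrnas, self.n_mirnas):
            raise ValueError("more blocks than entities on some axis")
        if self.dag_depth < 2:
            raise ValueError("dag_depth must be >= 2 (disease plus >=1 ancestor)")


@dataclass
class SyntheticDataset:
    """Generated edge lists, toy ontology text and ground truth."""

    spec: FixtureSpec
    disease_ids: tuple[str, ...]
    lncrna_ids: tuple[str, ...]
    mirna_ids: tuple[str, ...]
    blocks: dict[str, int]
    edges_dl: EdgeList
    edges_dm: EdgeList
    edges_lm: EdgeList
    mesh_text: str
    #: triangles of the noiseless block networks (id triples)
    true_triples: frozenset[tuple[str, str, str]]
    #: triangles of the noisy (training) networks
    train_triples: frozenset[tuple[str, str, str]]
    #: true triangles absent from training - recoverable "future" links
    heldout_triples: frozenset[tuple[str, str, str]] = field(init=False)

    def __post_init__(self) -> None:
        self.heldout_triples = self.true_triples - self.train_triples


def _block_of(i: int, n: int, n_blocks: int) -> int:
    return i * n_blocks // n


def _sample_bipartite(rng: np.random.Generator, blocks_a: np.ndarray,
                      blocks_b: np.ndarray, spec: FixtureSpec) -> np.ndarray:
    prob = np.where(blocks_a[:, None] == blocks_b[None, :],
                    spec.p_within, spec.p_between)
    return (rng.random(prob.shape) < prob).astype(np.int8)


def _flip(rng: np.random.Generator, adj: np.ndarray, rate: float) -> np.ndarray:
    flips = rng.random(adj.shape) < rate
    return np.where(flips, 1 - adj, adj).astype(np.int8)


def _triangles(a_dl: np.ndarray, a_dm: np.ndarray, a_lm: np.ndarray,
               d_ids, l_ids, m_ids) -> frozenset[tuple[str, str, str]]:
    out = set()
    for i in range(a_dl.shape[0]):
        mask = np.logical_and(np.outer(a_dl[i], a_dm[i]), a_lm.astype(bool))
        for j, k in zip(*np.nonzero(mask)):
            out.add((d_ids[i], l_ids[j], m_ids[k]))
    return frozenset(out)


def _edge_list(adj: np.ndarray, rows, cols, kinds) -> EdgeList:
    pairs = tuple((rows[i], cols[j]) for i, j in zip(*np.nonzero(adj)))
    return EdgeList(pairs=pairs, kinds=kinds)


def _mesh_text(disease_ids, blocks: dict[str, int], depth: int) -> str:
    """Toy descriptor file: block ancestor chains above each disease."""
    records = []
    seen_blocks = sorted({blocks[d] for d in disease_ids})
    for b in seen_blocks:
        chain = f"C{b + 1:02d}"
        records.append(f"*NEWRECORD\nMH = block-{b}\nMN = {chain}\n")
        for level in range(depth - 2):
            chain += ".500"
            records.append(
                f"*NEWRECORD\nMH = block-{b}-sub{level}\nMN = {chain}\n")
    for i, d in enumerate(disease_ids):
        chain = f"C{blocks[d] + 1:02d}" + ".500" * (depth - 2) + f".{i + 1:03d}"
        records.append(f"*NEWRECORD\nMH = {d}\nMN = {chain}\n")
    return "\n".join(records)


def generate(spec: FixtureSpec) -> SyntheticDataset:
    """Deterministically generate one dataset from a :class:`FixtureSpec`."""
    rng = np.random.default_rng(spec.seed)
    d_ids = tuple(f"d{i:02d}" for i in range(spec.n_diseases))
    l_ids = tuple(f"l{i:02d}" for i in range(spec.n_lncrnas))
    m_ids = tuple(f"m{i:02d}" for i in range(spec.n_mirnas))
    bd = np.asarray([_block_of(i, spec.n_diseases, spec.n_blocks)
                     for i in range(spec.n_diseases)])
    bl = np.asarray([_block_of(i, spec.n_lncrnas, spec.n_blocks)
                     for i in range(spec.n_lncrnas)])
    bm = np.asarray([_block_of(i, spec.n_mirnas, spec.n_blocks)
                     for i in range(spec.n_mirnas)])

    true_dl = _sample_bipartite(rng, bd, bl, spec)
    true_dm = _sample_bipartite(rng, bd, bm, spec)
    true_lm = _sample_bipartite(rng, bl, bm, spec)
    noisy_dl = _flip(rng, true_dl, spec.edge_noise)
    noisy_dm = _flip(rng, true_dm, spec.edge_noise)
    noisy_lm = _flip(rng, true_lm, spec.edge_noise)

    blocks = {**{d: int(b) for d, b in zip(d_ids, bd)},
              **{l: int(b) for l, b in zip(l_ids, bl)},
              **{m: int(b) for m, b in zip(m_ids, bm)}}
    return SyntheticDataset(
        spec=spec,
        disease_ids=d_ids, lncrna_ids=l_ids, mirna_ids=m_ids,
        blocks=blocks,
        edges_dl=_edge_list(noisy_dl, d_ids, l_ids, ("disease", "lncRNA")),
        edges_dm=_edge_list(noisy_dm, d_ids, m_ids, ("disease", "miRNA")),
        edges_lm=_edge_list(noisy_lm, l_ids, m_ids, ("lncRNA", "miRNA")),
        mesh_text=_mesh_text(d_ids, blocks, spec.dag_depth),
        true_triples=_triangles(true_dl.astype(bool), true_dm.astype(bool),
                                true_lm, d_ids, l_ids, m_ids),
        train_triples=_triangles(noisy_dl.astype(bool), noisy_dm.astype(bool),
                                 noisy_lm, d_ids, l_ids, m_ids),
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write edge lists, descriptor file and ground truth as TSV/ASCII."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "disease_lncrna": outdir / "disease_lncrna.tsv",
        "disease_mirna": outdir / "disease_mirna.tsv",
        "lncrna_mirna": outdir / "lncrna_mirna.tsv",
        "mesh": outdir / "mesh.txt",
        "true_triples": outdir / "true_triples.tsv",
        "heldout_triples": outdir / "heldout_triples.tsv",
    }
    for key, edges in (("disease_lncrna", dataset.edges_dl),
                       ("disease_mirna", dataset.edges_dm),
                       ("lncrna_mirna", dataset.edges_lm)):
        lines = [f"# {edges.kinds[0]}\t{edges.kinds[1]}"]
        lines += [f"{a}\t{b}" for a, b in edges.pairs]
        paths[key].write_text("\n".join(lines) + "\n", encoding="utf-8")
    paths["mesh"].write_text(dataset.mesh_text, encoding="utf-8")
    for key, triples in (("true_triples", dataset.true_triples),
                         ("heldout_triples", dataset.heldout_triples)):
        lines = ["# disease\tlncRNA\tmiRNA"]
        lines += [f"{d}\t{l}\t{m}" for d, l, m in sorted(triples)]
        paths[key].write_text("\n".join(lines) + "\n", encoding="utf-8")
    return paths


def planted_tucker_tensor(shape: tuple[int, int, int],
                          ranks: tuple[int, int, int],
                          seed: int) -> tuple[np.ndarray, np.ndarray,
                                              list[np.ndarray]]:
    """Exact nonnegative Tucker tensor for decomposition recovery tests."""
    from .tucker import tucker_to_tensor

    rng = np.random.default_rng(seed)
    factors = [rng.uniform(0.1, 1.1, size=(n, r))
               for n, r in zip(shape, ranks)]
    core = rng.uniform(0.1, 1.1, size=ranks)
    return tucker_to_tensor(core, factors), core, factors
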