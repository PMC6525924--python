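"""TSV/JSON writers and readers for pipeline artifacts."""

from __future__ import annotations

import json
import os
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .networks import AssociationTensor
from .similarity import SimilarityMatrix


def write_tensor(tensor: AssociationTensor, outdir: str | Path) -> dict[str, Path]:
    """Sparse triple-list TSV plus one index-map TSV per axis."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    i, j, k = np.nonzero(tensor.values)
    triples = pd.DataFrame({
        "disease": [tensor.disease_ids[x] for x in i],
        "lncRNA": [tensor.lncrna_ids[x] for x in j],
        "miRNA": [tensor.mirna_ids[x] for x in k],
        "value": tensor.values[i, j, k],
    })
    paths = {"triples": outdir / "tensor_triples.tsv"}
    triples.to_csv(paths["triples"], sep="\t", index=False)
    for axis, ids in (("disease", tensor.disease_ids),
                      ("lncrna", tensor.lncrna_ids),
                      ("mirna", tensor.mirna_ids)):
        path = outdir / f"index_{axis}.tsv"
        pd.DataFrame({"index": range(len(ids)), "id": ids}).to_csv(
            path, sep="\t", index=False)
        paths[f"index_{axis}"] = path
    return paths


def read_tensor(indir: str | Path) -> AssociationTensor:
    indir = Path(indir)
    ids = {}
    for axis in ("disease", "lncrna", "mirna"):
        df = pd.read_csv(indir / f"index_{axis}.tsv", sep="\t", dtype={"id": str})
        ids[axis] = tuple(df.sort_values("index")["id"])
    values = np.zeros((len(ids["disease"]), len(ids["lncrna"]), len(ids["mirna"])))
    lookup = {axis: {name: i for i, name in enumerate(ids[axis])}
              for axis in ids}
    triples = pd.read_csv(indir / "tensor_triples.tsv", sep="\t",
                          dtype={"disease": str, "lncRNA": str, "miRNA": str})
    for row in triples.itertuples(index=False):
        values[lookup["disease"][row.disease],
               lookup["lncrna"][row.lncRNA],
               lookup["mirna"][row.miRNA]] = row.value
    return AssociationTensor(values, ids["disease"], ids["lncrna"], ids["mirna"])


def write_similarity(matrix: SimilarityMatrix, path: str | Path) -> Path:
    """Square similarity TSV with an identifier header row and column."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(matrix.values, index=matrix.ids, columns=matrix.ids).to_csv(
        path, sep="\t", index_label=matrix.kind)
    return path


def write_rankings(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)
    return path


def write_manifest(manifest: dict, path: str | Path) -> Path:
    """Atomic JSON manifest (written to a temp file, then renamed)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(manifest)
    payload.setdefault("written_at", time.strftime("%Y-%m-%dT%H:%M:%S%z"))
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str)
                   + "\n", encoding="utf-8")
    os.replace(tmp, path)
    return path
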