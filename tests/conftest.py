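"""Shared fixtures: the default synthetic dataset and small helpers."""

from __future__ import annotations

import io
from types import SimpleNamespace

import numpy as np
import pytest

from trilink import (FixtureSpec, build_tensor_from_edge_lists,
                     compute_similarities, generate, parse_mesh)


@pytest.fixture(scope="session")
def default_data():
    """Default planted-block dataset (seed 1) with tensor and similarities."""
    ds = generate(FixtureSpec(seed=1))
    tensor, tri = build_tensor_from_edge_lists(ds.edges_dl, ds.edges_dm,
                                               ds.edges_lm)
    mesh = parse_mesh(io.StringIO(ds.mesh_text))
    bundle = compute_similarities(tri, mesh)
    return SimpleNamespace(ds=ds, tensor=tensor, tri=tri, mesh=mesh,
                           bundle=bundle)


@pytest.fixture(scope="session")
def small_data():
    """A miniature dataset for tests that refit the pipeline many times."""
    ds = generate(FixtureSpec(seed=2, n_diseases=5, n_lncrnas=4, n_mirnas=5,
                              p_within=0.9))
    tensor, tri = build_tensor_from_edge_lists(ds.edges_dl, ds.edges_dm,
                                               ds.edges_lm)
    mesh = parse_mesh(io.StringIO(ds.mesh_text))
    bundle = compute_similarities(tri, mesh)
    return SimpleNamespace(ds=ds, tensor=tensor, tri=tri, mesh=mesh,
                           bundle=bundle)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_binary(rng: np.random.Generator, shape, p: float = 0.4,
                  ensure_nonzero: bool = True) -> np.ndarray:
    """Random 0/1 array, guaranteed to contain at least one 1."""
    arr = (rng.random(shape) < p).astype(float)
    if ensure_nonzero and arr.sum() == 0:
        idx = tuple(rng.integers(0, s) for s in arr.shape)
        arr[idx] = 1.0
    return arr
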