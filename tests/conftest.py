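"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from eegmst.io_preprocess import Recording
from eegmst.mst_topology import SpanningTree


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


# ---------------------------------------------------------------- tree builders

def make_chain(n: int, weight: float = 0.1) -> SpanningTree:
    return SpanningTree(
        n_nodes=n,
        edges=[(i, i + 1, weight) for i in range(n - 1)],
        node_labels=[f"n{i}" for i in range(n)],
    )


def make_star(n: int, weight: float = 0.1) -> SpanningTree:
    return SpanningTree(
        n_nodes=n,
        edges=[(0, i, weight) for i in range(1, n)],
        node_labels=[f"n{i}" for i in range(n)],
    )


# -------------------------------------------------- brute-force MST oracle

def prufer_decode(seq: tuple[int, ...], n: int) -> list[tuple[int, int]]:
    """Decode a Prüfer sequence into the edge list of its labelled tree."""
    degree = [1] * n
    for v in seq:
        degree[v] += 1
    edges = []
    leaves = sorted(i for i in range(n) if degree[i] == 1)
    import heapq

    heapq.heapify(leaves)
    for v in seq:
        leaf = heapq.heappop(leaves)
        edges.append((leaf, v))
        degree[v] -= 1
        if degree[v] == 1:
            heapq.heappush(leaves, v)
    u = heapq.heappop(leaves)
    w = heapq.heappop(leaves)
    edges.append((u, w))
    return edges


def all_labelled_trees(n: int) -> np.ndarray:
    """All n^(n−2) labelled spanning trees on n nodes, as (count, n−1, 2)."""
    trees = [
        prufer_decode(seq, n)
        for seq in itertools.product(range(n), repeat=n - 2)
    ]
    return np.asarray(trees, dtype=np.int64)


def brute_force_mst_weight(weights: np.ndarray, trees: np.ndarray | None = None) -> float:
    """Minimum total weight over exhaustive enumeration of labelled trees."""
    n = weights.shape[0]
    if trees is None:
        trees = all_labelled_trees(n)
    totals = weights[trees[:, :, 0], trees[:, :, 1]].sum(axis=1)
    return float(totals.min())


# -------------------------------------------------------------- signal helpers

def two_channel_recording(
    lag: float,
    freq: float = 10.0,
    rate: float = 250.0,
    duration: float = 80.0,
) -> Recording:
    """Two noiseless sinusoids with a constant phase lag."""
    t = np.arange(int(duration * rate)) / rate
    x = np.cos(2 * np.pi * freq * t)
    y = np.cos(2 * np.pi * freq * t - lag)
    return Recording(
        subject_id="pair",
        samples=np.vstack([x, y]),
        rate=rate,
        channel_labels=["a", "b"],
        channel_kinds=["EEG", "EEG"],
    )


def random_symmetric_matrix(
    n: int, rng: np.random.Generator, low: float = 0.0, high: float = 1.0
) -> np.ndarray:
    """Symmetric matrix with zero diagonal and i.i.d. uniform off-diagonal."""
    values = rng.uniform(low, high, size=(n, n))
    values = np.triu(values, k=1)
    return values + values.T
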