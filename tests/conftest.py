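"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from silkshift.phyloexpr.trees import GeneTree, Node


def random_tree(n_tips: int, rng: np.random.Generator, min_len=0.1, max_len=2.0) -> GeneTree:
    """Random rooted binary tree by sequential pairwise joining."""
    nodes = [Node(name=f"T{i}", length=float(rng.uniform(min_len, max_len))) for i in range(n_tips)]
    cnt = itertools.count()
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[j], nodes[i]
        p = Node(name=f"I{next(cnt)}", length=float(rng.uniform(min_len, max_len)))
        p.add_child(a)
        p.add_child(b)
        nodes = [x for x in nodes if x not in (a, b)] + [p]
    root = nodes[0]
    root.length = 0.0
    return GeneTree(root)


def _root_path(nd: Node) -> list[Node]:
    path = []
    while nd is not None:
        path.append(nd)
        nd = nd.parent
    return path


def _dist_from_root(nd: Node) -> float:
    d = 0.0
    while nd.parent is not None:
        d += nd.length
        nd = nd.parent
    return d


def gls_ancestral_oracle(tree: GeneTree, tip_values: dict[str, float]) -> dict[str, float]:
    """Brute-force GLS ancestral states by explicit covariance inversion.

    Independent of the package's Laplacian-solve implementation: builds the
    full BM tip covariance (shared root-to-MRCA path lengths), estimates the
    root by GLS, and conditions each internal node on the tips.
    """
    tips = tree.tips()
    internals = tree.internal_nodes()

    def mrca_depth(a: Node, b: Node) -> float:
        ids_a = {id(x) for x in _root_path(a)}
        mrca = next(x for x in _root_path(b) if id(x) in ids_a)
        return _dist_from_root(mrca)

    n = len(tips)
    C = np.empty((n, n))
    for i, a in enumerate(tips):
        for j, b in enumerate(tips):
            C[i, j] = _dist_from_root(a) if a is b else mrca_depth(a, b)
    y = np.array([tip_values[t.label] for t in tips])
    Ci = np.linalg.inv(C)
    one = np.ones(n)
    mu = float(one @ Ci @ y / (one @ Ci @ one))
    out: dict[str, float] = {}
    for nd in internals:
        if nd.parent is None:
            out[nd.label] = mu
        else:
            cov = np.array([mrca_depth(nd, t) for t in tips])
            out[nd.label] = float(mu + cov @ Ci @ (y - mu * one))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
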