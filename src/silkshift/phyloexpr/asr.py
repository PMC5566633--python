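"""Maximum-likelihood ancestral expression states under Brownian motion.

The ML ancestral states minimize ``sum((x_child - x_parent)^2 / t_branch)``
over all branches with tip values fixed, which for a Gaussian process equals
the GLS conditional expectation ``E[x_internal | tips]``.  The estimates are
obtained by solving the (tree-Laplacian) normal equations; this matches the
explicit covariance-matrix GLS solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .trees import GeneTree, Node, TreeError

__all__ = [
    "AncestralStates",
    "AsrSolver",
    "bm_ancestral_states",
    "classify_node_state",
    "NOT_SILK",
    "MULTIPLE",
]

NOT_SILK = "NOT_SILK"
MULTIPLE = "MULTIPLE"


@dataclass
class AncestralStates:
    """ML node values for one continuous character plus the BM rate estimate."""

    values: dict[str, float]  # node label -> ML value (tips: observed)
    sigma2: float


class AsrSolver:
    """Pre-factorized BM reconstruction operator for one tree.

    Building the solver is O(n^3) in the number of internal nodes; each
    subsequent reconstruction is a pair of triangular solves, which makes
    repeated use (permutation/simulation nulls) cheap.

    Zero-length branches are replaced by ``eps = 1e-6 * tree depth`` so the
    covariance stays positive definite.
    """

    def __init__(self, tree: GeneTree):
        tips = tree.tips()
        internals = tree.internal_nodes()
        if not internals:
            raise TreeError("tree has no internal nodes")
        depth = tree.depth()
        if depth <= 0:
            raise TreeError("all branch lengths are zero")
        eps = 1e-6 * depth

        self.tree = tree
        self.tips = tips
        self.tip_labels = [t.label for t in tips]
        self.internals = internals
        self.internal_labels = [nd.label for nd in internals]
        i_index = {id(nd): k for k, nd in enumerate(internals)}
        t_index = {id(nd): k for k, nd in enumerate(tips)}

        n_int, n_tip = len(internals), len(tips)
        A = np.zeros((n_int, n_int))
        B = np.zeros((n_int, n_tip))  # rhs contribution of tip values

        def blen(nd: Node) -> float:
            return nd.length if nd.length > 0 else eps

        for k, nd in enumerate(internals):
            neighbors = list(nd.children)
            if nd.parent is not None:
                neighbors.append(nd.parent)
            for nb in neighbors:
                w = 1.0 / blen(nb if nb is not nd.parent else nd)
                A[k, k] += w
                if nb.is_leaf:
                    B[k, t_index[id(nb)]] += w
                else:
                    A[k, i_index[id(nb)]] -= w
        self._lu = lu_factor(A)
        self._B = B
        self._i_index = i_index
        self._blen = blen

        # per-internal-node child lookups for vectorized sister differences:
        # (is_tip flag, index into the tip or internal arrays) per child slot
        c_tip = np.zeros((n_int, 2), dtype=bool)
        c_idx = np.zeros((n_int, 2), dtype=np.intp)
        for k, nd in enumerate(internals):
            kids = nd.children[:2]
            if len(kids) == 1:  # unary node: zero contribution
                kids = [kids[0], kids[0]]
            for slot, ch in enumerate(kids):
                if ch.is_leaf:
                    c_tip[k, slot] = True
                    c_idx[k, slot] = t_index[id(ch)]
                else:
                    c_idx[k, slot] = i_index[id(ch)]
        self._child_is_tip = c_tip
        # separate safe index arrays (np.where evaluates both branches)
        self._child_tip_idx = np.where(c_tip, c_idx, 0)
        self._child_int_idx = np.where(c_tip, 0, c_idx)

    def reconstruct(self, tip_values: np.ndarray) -> np.ndarray:
        """ML internal-node values (ordered as ``internal_labels``).

        ``tip_values`` may be a vector or a (n_tips, m) matrix of m
        independent characters; the result has matching trailing shape.
        """
        return lu_solve(self._lu, self._B @ np.asarray(tip_values, dtype=float))

    def _child_values(self, tip_values: np.ndarray, internal: np.ndarray, slot: int):
        return np.where(
            self._child_is_tip[:, slot, None],
            tip_values[self._child_tip_idx[:, slot]],
            internal[self._child_int_idx[:, slot]],
        )

    def sister_difference_sums(self, tip_values: np.ndarray) -> np.ndarray:
        """Sum over internal nodes of |value(child1) - value(child2)|.

        Child values are observed at tips and reconstructed at internal
        nodes (the Fritz & Purvis nodal-difference statistic).  Accepts a
        (n_tips, m) matrix and returns m sums.
        """
        X = np.asarray(tip_values, dtype=float)
        squeeze = X.ndim == 1
        if squeeze:
            X = X[:, None]
        internal = self.reconstruct(X)
        diffs = np.abs(self._child_values(X, internal, 0) - self._child_values(X, internal, 1))
        out = diffs.sum(axis=0)
        return out[0] if squeeze else out

    def sister_difference_sum(self, tip_values: np.ndarray) -> float:
        return float(self.sister_difference_sums(np.asarray(tip_values, dtype=float)))

    def sigma2_ml(self, tip_values: np.ndarray) -> float:
        """ML Brownian-motion rate from the branchwise squared changes."""
        tip_values = np.asarray(tip_values, dtype=float)
        internal = self.reconstruct(tip_values)
        values = {id(nd): internal[k] for k, nd in enumerate(self.internals)}
        for k, t in enumerate(self.tips):
            values[id(t)] = tip_values[k]
        ss = 0.0
        n_branch = 0
        for parent, child in self.tree.branches():
            ss += (values[id(child)] - values[id(parent)]) ** 2 / self._blen(child)
            n_branch += 1
        return ss / n_branch if n_branch else 0.0


def bm_ancestral_states(tree: GeneTree, tip_values: dict[str, float]) -> AncestralStates:
    """ML ancestral states under Brownian motion for one character.

    ``tip_values`` maps tip labels (``species:transcript``) to observed
    values; every tip must be present and finite.
    """
    solver = AsrSolver(tree)
    try:
        x = np.array([tip_values[lbl] for lbl in solver.tip_labels], dtype=float)
    except KeyError as exc:
        raise KeyError(f"missing tip value for {exc.args[0]!r}") from exc
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite tip values")
    internal = solver.reconstruct(x)
    values = dict(zip(solver.tip_labels, x))
    values.update(zip(solver.internal_labels, internal))
    return AncestralStates(values=values, sigma2=solver.sigma2_ml(x))


def classify_node_state(
    tissue_values,
    silk_tissues,
    non_silk_tissues,
    fold: float = 2.0,
    majority: float = 0.5,
) -> str:
    """Categorical expression state of one node from its per-tissue values.

    NOT_SILK unless the mean over silk-gland tissues is strictly more than
    ``fold`` times the mean over non-silk tissues; otherwise the gland
    holding strictly more than ``majority`` of the silk-tissue total, else
    MULTIPLE.  Negative (reconstructed) values are floored at 0 first.
    """
    silk_tissues = list(silk_tissues)
    non_silk_tissues = list(non_silk_tissues)
    if not silk_tissues or not non_silk_tissues:
        raise ValueError("need at least one silk and one non-silk tissue")
    silk = np.array([max(float(tissue_values[t]), 0.0) for t in silk_tissues])
    non_silk = np.array([max(float(tissue_values[t]), 0.0) for t in non_silk_tissues])
    if silk.mean() <= fold * non_silk.mean():
        return NOT_SILK
    total = silk.sum()
    shares = silk / total
    best = int(np.argmax(shares))
    if shares[best] > majority:
        return silk_tissues[best]
    return MULTIPLE
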