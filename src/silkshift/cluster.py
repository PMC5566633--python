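"""Correlation-based hierarchical clustering, bootstrap support, and PCA.

Distances are 1 - Spearman's rho.  Items are sorted lexicographically by
label before clustering, which makes dendrograms invariant to input order
(deterministic tie-breaking).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

__all__ = [
    "CorrelationMatrix",
    "Dendrogram",
    "ClusterAssignment",
    "spearman_matrix",
    "hierarchical_cluster",
    "cut_and_assign",
    "bootstrap_support",
    "pca_projection",
    "expression_share",
]

MULTIPLE_GLANDS = "multiple glands"


@dataclass
class CorrelationMatrix:
    values: pd.DataFrame  # symmetric, diagonal 1
    constant_items: list[str] = field(default_factory=list)  # rho set to 0

    @property
    def labels(self) -> list[str]:
        return list(self.values.index)


@dataclass
class Dendrogram:
    """A scipy linkage matrix over label-sorted items."""

    linkage_matrix: np.ndarray
    labels: list[str]  # sorted; leaf i of the linkage = labels[i]
    method: str

    def clades(self) -> list[frozenset[str]]:
        """Non-trivial clades (unordered tip sets, 2 <= size < n)."""
        n = len(self.labels)
        members: dict[int, frozenset[str]] = {
            i: frozenset([lbl]) for i, lbl in enumerate(self.labels)
        }
        out = []
        for i, row in enumerate(self.linkage_matrix):
            merged = members[int(row[0])] | members[int(row[1])]
            members[n + i] = merged
            if 2 <= len(merged) < n:
                out.append(merged)
        return out

    def cut(self, k: int) -> pd.Series:
        if k < 1:
            raise ValueError("k must be >= 1")
        if k > len(self.labels):
            raise ValueError("k exceeds the number of items")
        flat = cut_tree(self.linkage_matrix, n_clusters=k).ravel()
        return pd.Series(flat, index=self.labels, name="group")


@dataclass
class ClusterAssignment:
    groups: pd.Series  # item -> group id
    group_labels: dict[int, str]  # group id -> gland id or "multiple glands"
    dendrogram: Dendrogram

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.groups,
                "label": [self.group_labels[g] for g in self.groups],
            }
        )


def spearman_matrix(profiles: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Spearman correlations between rows (items x features).

    Ties take average ranks.  Items constant across features have undefined
    correlations; these are recorded as 0 with a warning and the item is
    listed in ``constant_items``.
    """
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 items")
    if profiles.shape[1] < 2:
        raise ValueError("need at least 2 features")
    X = profiles.to_numpy(dtype=float)
    constant = [
        str(profiles.index[i]) for i in range(X.shape[0]) if np.ptp(X[i]) == 0
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = spearmanr(X, axis=1).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-item case to a scalar
        r = float(rho)
        rho = np.array([[1.0, r], [r, 1.0]])
    if constant:
        warnings.warn(
            f"constant profiles, correlation set to 0: {constant}", stacklevel=2
        )
        rho = np.nan_to_num(rho, nan=0.0)
    np.fill_diagonal(rho, 1.0)
    values = pd.DataFrame(rho, index=profiles.index, columns=profiles.index)
    return CorrelationMatrix(values=values, constant_items=constant)


def hierarchical_cluster(corr: CorrelationMatrix, method: str = "average") -> Dendrogram:
    """Agglomerative clustering on distance 1 - rho.

    Items are reordered lexicographically by label first so the result does
    not depend on input order.
    """
    if method not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {method!r}")
    order = sorted(str(lbl) for lbl in corr.values.index)
    vals = corr.values.loc[order, order].to_numpy(dtype=float)
    dist = 1.0 - vals
    if np.isnan(dist).any():
        bad = [
            (order[i], order[j])
            for i, j in zip(*np.where(np.isnan(dist)))
            if i < j
        ]
        raise ValueError(f"NaN distances between: {bad}")
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    Z = linkage(squareform(dist, checks=False), method=method)
    return Dendrogram(linkage_matrix=Z, labels=order, method=method)


def cut_and_assign(
    dendrogram: Dendrogram,
    gland_shares: pd.DataFrame,
    k: int,
    majority: float = 0.5,
) -> ClusterAssignment:
    """Cut into exactly ``k`` groups and assign each to its majority gland.

    ``gland_shares`` is item x gland summed mean FPKM (or shares).  A group
    is labeled with a gland only when that gland holds strictly more than
    ``majority`` of the group's summed expression; otherwise it is labeled
    "multiple glands".
    """
    groups = dendrogram.cut(k)
    shares = gland_shares.reindex(groups.index)
    labels: dict[int, str] = {}
    for g in sorted(groups.unique()):
        total = shares.loc[groups.index[groups == g]].sum(axis=0)
        grand = total.sum()
        if grand <= 0:
            labels[g] = MULTIPLE_GLANDS
            continue
        frac = total / grand
        best = frac.idxmax()
        labels[g] = str(best) if frac.loc[best] > majority else MULTIPLE_GLANDS
    return ClusterAssignment(groups=groups, group_labels=labels, dendrogram=dendrogram)


def bootstrap_support(
    profiles: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
    method: str = "average",
) -> dict[frozenset[str], float]:
    """Bootstrap clade support by resampling feature columns with replacement.

    Reclusters each resample and reports, for every non-trivial clade of the
    original dendrogram, the fraction of replicates in which the same
    unordered tip set appears.  Resamples features only, never items.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = hierarchical_cluster(spearman_matrix(profiles), method=method)
    target = base.clades()
    hits = {c: 0 for c in target}
    n_feat = profiles.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, n_feat, size=n_feat)
        boot = profiles.iloc[:, cols]
        boot.columns = range(n_feat)
        try:
            clades = set(hierarchical_cluster(spearman_matrix(boot), method=method).clades())
        except ValueError:
            continue  # degenerate resample (all-constant features)
        for c in target:
            if c in clades:
                hits[c] += 1
    return {c: hits[c] / n_boot for c in target}


def pca_projection(profiles: pd.DataFrame, n_components: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered (not scaled) PCA of items x features.

    Returns component scores and explained-variance fractions.  The sign of
    each component is fixed so its largest-magnitude loading is positive.
    """
    X = profiles.to_numpy(dtype=float)
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    Xc = X - X.mean(axis=0, keepdims=True)
    if np.allclose(Xc, 0):
        raise ValueError("degenerate all-constant input")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    signs = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    signs[signs == 0] = 1.0
    U, Vt = U * signs, Vt * signs[:, None]
    scores = U[:, :n_components] * s[:n_components]
    evr = (s**2) / (s**2).sum()
    return (
        pd.DataFrame(
            scores,
            index=profiles.index,
            columns=[f"PC{i+1}" for i in range(n_components)],
        ),
        evr[:n_components],
    )


def expression_share(
    tissue_profile: pd.DataFrame, categories: pd.Series, other: str = "other"
) -> pd.DataFrame:
    """Per-tissue share of total mean FPKM by transcript category.

    ``tissue_profile`` is transcript x tissue; transcripts absent from
    ``categories`` fall in the ``other`` bucket.  Shares sum to 1 per
    tissue; a tissue with zero total FPKM is an error.
    """
    cats = categories.reindex(tissue_profile.index).fillna(other)
    sums = tissue_profile.groupby(cats.to_numpy()).sum()  # category x tissue
    totals = sums.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"tissues with zero total FPKM: {bad}")
    return (sums / totals).T  # tissue x category
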