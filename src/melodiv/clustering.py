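"""UPGMA trees, principal coordinate analysis, and trait standardization/PCA.

UPGMA merges the closest pair of clusters at each step, placing the new node
at half the merge distance, and updates distances by the size-weighted
arithmetic average.  Ties on the minimum distance are broken by merging the
pair whose (lexicographically smallest member) labels sort first, so the
tree is a deterministic function of the distance matrix regardless of input
order.

PCoA applies Gower double-centering to -D²/2 and eigendecomposes; axes with
negative eigenvalues (possible for non-Euclidean band-sharing distances) are
reported but dropped from the coordinates, and variance explained is taken
over the positive eigenvalues only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SKPCA

from .data_model import DataError, DistanceMatrix

__all__ = [
    "TreeNode",
    "UltrametricTree",
    "OrdinationResult",
    "upgma",
    "to_newick",
    "cut_tree",
    "pcoa",
    "standardize",
    "pca",
]


@dataclass
class TreeNode:
    height: float
    children: tuple["TreeNode", ...] = ()
    label: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class UltrametricTree:
    """Binary merge tree; internal node heights are half the merge distance."""

    root: TreeNode
    # merge history: (height, members of one side, members of the other)
    merges: list[tuple[float, frozenset, frozenset]] = field(default_factory=list)

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def internal_heights(self) -> list[float]:
        out = []

        def walk(n: TreeNode) -> None:
            if not n.is_leaf:
                out.append(n.height)
                for c in n.children:
                    walk(c)

        walk(self.root)
        return out


def upgma(d: DistanceMatrix) -> UltrametricTree:
    """Size-weighted average-linkage agglomeration of a distance matrix."""
    if d.n < 2:
        if d.n == 1:
            return UltrametricTree(TreeNode(0.0, label=d.labels[0]))
        raise DataError("need at least one taxon")
    if np.isnan(d.values).any():
        raise DataError("distance matrix contains NaN")

    # active clusters keyed by their lexicographically smallest member label
    nodes: dict[str, TreeNode] = {
        lab: TreeNode(0.0, label=lab) for lab in d.labels
    }
    sizes: dict[str, int] = {lab: 1 for lab in d.labels}
    dist: dict[frozenset, float] = {}
    for i in range(d.n):
        for j in range(i + 1, d.n):
            dist[frozenset((d.labels[i], d.labels[j]))] = float(d.values[i, j])
    merges: list[tuple[float, frozenset, frozenset]] = []

    while len(nodes) > 1:
        keys = sorted(nodes)
        best: tuple[float, str, str] | None = None
        for a_i, a in enumerate(keys):
            for b in keys[a_i + 1 :]:
                val = dist[frozenset((a, b))]
                cand = (val, a, b)
                if best is None or cand < best:
                    best = cand
        assert best is not None
        dmin, a, b = best
        node = TreeNode(dmin / 2.0, children=(nodes[a], nodes[b]))
        merges.append(
            (dmin / 2.0, frozenset(nodes[a].leaves()), frozenset(nodes[b].leaves()))
        )
        new_key = min(a, b)
        na, nb = sizes[a], sizes[b]
        for other in keys:
            if other in (a, b):
                continue
            dav = (
                na * dist[frozenset((a, other))] + nb * dist[frozenset((b, other))]
            ) / (na + nb)
            dist[frozenset((new_key, other))] = dav
        del nodes[a], nodes[b], sizes[a], sizes[b]
        nodes[new_key] = node
        sizes[new_key] = na + nb

    return UltrametricTree(next(iter(nodes.values())), merges)


def to_newick(t: UltrametricTree, precision: int = 6) -> str:
    """Newick serialization with branch lengths parent height - child height."""

    def fmt(x: float) -> str:
        return f"{x:.{precision}g}"

    def walk(n: TreeNode, parent_height: float | None) -> str:
        if n.is_leaf:
            body = n.label or ""
        else:
            body = "(" + ",".join(walk(c, n.height) for c in n.children) + ")"
        if parent_height is None:
            return body
        return f"{body}:{fmt(parent_height - n.height)}"

    return walk(t.root, None) + ";"


def cut_tree(t: UltrametricTree, n_clusters: int) -> dict[str, int]:
    """Partition leaves into ``n_clusters`` by undoing the last merges.

    Returns leaf label -> cluster index (0-based, ordered by each cluster's
    smallest member label).  This is the lowest-height cut that yields the
    requested number of connected components.
    """
    leaves = t.leaves()
    if not 1 <= n_clusters <= len(leaves):
        raise DataError(
            f"n_clusters must be in [1, {len(leaves)}], got {n_clusters}"
        )
    # replay merges until n_clusters components remain
    comp: dict[str, frozenset] = {lab: frozenset((lab,)) for lab in leaves}
    n_comp = len(leaves)
    for _, left, right in t.merges:
        if n_comp == n_clusters:
            break
        merged = left | right
        for lab in merged:
            comp[lab] = merged
        n_comp -= 1
    clusters = sorted({c for c in comp.values()}, key=lambda c: min(c))
    index = {c: k for k, c in enumerate(clusters)}
    return {lab: index[comp[lab]] for lab in leaves}


@dataclass
class OrdinationResult:
    """Coordinates, eigenvalues, and variance explained for PCoA/PCA."""

    coordinates: pd.DataFrame  # items x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    variance_explained: np.ndarray  # fraction per retained axis

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def pcoa(d: DistanceMatrix, n_axes: int = 2) -> OrdinationResult:
    """Principal coordinate analysis via Gower double-centering."""
    dd = d.values
    n = d.n
    b = -0.5 * dd**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ b @ j
    b = (b + b.T) / 2.0
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = max(1e-12, 1e-9 * max(abs(eigval[0]), 1.0))
    positive = eigval > tol
    n_pos = int(positive.sum())
    if n_axes > n_pos:
        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; "
            "truncating",
            stacklevel=2,
        )
        n_axes = n_pos
    coords = eigvec[:, :n_axes] * np.sqrt(np.maximum(eigval[:n_axes], 0.0))
    pos_sum = eigval[positive].sum()
    var_exp = (
        eigval[:n_axes] / pos_sum if pos_sum > 0 else np.zeros(n_axes)
    )
    cols = [f"Axis{k + 1}" for k in range(n_axes)]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=d.labels, columns=cols),
        eigenvalues=eigval,
        variance_explained=np.asarray(var_exp, dtype=float),
    )


def standardize(traits: pd.DataFrame) -> pd.DataFrame:
    """Column-wise (x - mean) / sd with the n-1 sample standard deviation."""
    x = traits.astype(float)
    sd = x.std(ddof=1)
    bad = sd[~(sd > 0)].index.tolist()
    if bad:
        raise DataError(f"zero-variance trait(s): {bad}")
    return (x - x.mean()) / sd


def pca(x: pd.DataFrame | np.ndarray, n_axes: int = 2) -> OrdinationResult:
    """Principal component analysis of a standardized trait matrix."""
    arr = np.asarray(x, dtype=float)
    if arr.shape[0] < 2:
        raise DataError("PCA needs at least 2 samples")
    n_axes = min(n_axes, min(arr.shape))
    model = _SKPCA(n_components=min(arr.shape), svd_solver="full")
    scores = model.fit_transform(arr)
    index = x.index if isinstance(x, pd.DataFrame) else pd.RangeIndex(arr.shape[0])
    cols = [f"PC{k + 1}" for k in range(n_axes)]
    return OrdinationResult(
        coordinates=pd.DataFrame(scores[:, :n_axes], index=index, columns=cols),
        eigenvalues=model.explained_variance_.copy(),
        variance_explained=model.explained_variance_ratio_[:n_axes].copy(),
    )
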