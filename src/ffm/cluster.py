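"""Ward-linkage hierarchical clustering with bootstrap clade support.

Clustering uses Euclidean distances with Ward's minimum-variance criterion
applied to unsquared distances (the "ward.D2" variant). Clade support is the
plain bootstrap probability: features (columns, when clustering rows) are
resampled with replacement, the tree is rebuilt, and each original clade's
support is the fraction of replicate trees in which its exact leaf set
reappears.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator


def _clades(linkage: np.ndarray, labels: list[str]) -> list[frozenset[str]]:
    """Leaf set of every internal node of a linkage matrix, in merge order."""
    n = len(labels)
    sets: dict[int, frozenset[str]] = {i: frozenset([labels[i]]) for i in range(n)}
    out = []
    for k, (a, b, _, _) in enumerate(linkage):
        sets[n + k] = sets[int(a)] | sets[int(b)]
        out.append(sets[n + k])
    return out


@dataclass
class SupportedDendrogram:
    """Binary merge tree over labelled leaves, with optional clade support.

    ``linkage`` is a scipy linkage matrix over ``labels``; ``support`` maps
    each internal node's frozen leaf set to its bootstrap probability.
    """

    linkage: np.ndarray
    labels: list[str]
    support: dict[frozenset[str], float] = field(default_factory=dict)
    n_boot: int = 0
    seed: int | None = None

    @property
    def clades(self) -> list[frozenset[str]]:
        return _clades(self.linkage, self.labels)

    def support_table(self) -> pd.DataFrame:
        rows = [
            {"clade": ";".join(sorted(c)), "size": len(c), "support": self.support.get(c, np.nan)}
            for c in self.clades
        ]
        return pd.DataFrame(rows)

    def to_newick(self, digits: int = 6) -> str:
        """Serialize as Newick: branch lengths from merge heights, bootstrap
        support (if computed) as internal node labels."""
        tree = hierarchy.to_tree(self.linkage)
        clades = {len(self.labels) + k: c for k, c in enumerate(self.clades)}

        def height(node) -> float:
            return 0.0 if node.is_leaf() else float(node.dist)

        def walk(node, parent_height: float) -> str:
            bl = parent_height - height(node)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{bl:.{digits}g}"
            left = walk(node.left, height(node))
            right = walk(node.right, height(node))
            label = ""
            if self.support:
                s = self.support.get(clades[node.id])
                if s is not None:
                    label = f"{s:.{digits}g}"
            return f"({left},{right}){label}:{bl:.{digits}g}"

        root = f"({walk(tree.left, height(tree))},{walk(tree.right, height(tree))});"
        return root


def _ward_linkage(X: np.ndarray) -> np.ndarray:
    return hierarchy.linkage(X, method="ward", metric="euclidean")


class WardClusterer(BaseEstimator):
    """Ward.D2 agglomerative clustering with optional bootstrap support.

    Parameters
    ----------
    axis : {"rows", "columns"}
        Cluster the rows of the input (resampling columns) or its columns
        (resampling rows).
    n_boot : int
        Bootstrap replicates; 0 fits the tree without support values.
    random_state : int or None
        Seed for the resampling RNG; fixed seed => bit-reproducible output.

    Attributes
    ----------
    dendrogram_ : SupportedDendrogram — the fitted tree (+ support if n_boot > 0).

    Notes
    -----
    Leaves are sorted lexicographically by label before linkage so that
    merge ties are broken deterministically.
    """

    def __init__(
        self,
        axis: str = "rows",
        n_boot: int = 0,
        random_state: int | None = None,
    ):
        self.axis = axis
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "WardClusterer":
        if self.axis not in ("rows", "columns"):
            raise ValueError(f"axis must be 'rows' or 'columns', got {self.axis!r}")
        if self.n_boot < 0:
            raise ValueError("n_boot must be >= 0")
        X = pd.DataFrame(X)
        if self.axis == "columns":
            X = X.T
        if X.isna().any().any():
            raise ValueError("clustering input has missing cells")
        labels = [str(v) for v in X.index]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels")
        if len(labels) < 2:
            raise ValueError("need at least 2 leaves")

        order = np.argsort(labels, kind="stable")  # lexicographic tie determinism
        labels = [labels[i] for i in order]
        values = X.to_numpy(dtype=float)[order]

        linkage = _ward_linkage(values)
        dendro = SupportedDendrogram(linkage=linkage, labels=labels)

        if self.n_boot > 0:
            if len(labels) < 3:
                raise ValueError("bootstrap support needs at least 3 leaves")
            rng = np.random.default_rng(self.random_state)
            counts = {c: 0 for c in dendro.clades}
            n_feat = values.shape[1]
            for _ in range(self.n_boot):
                idx = rng.integers(0, n_feat, size=n_feat)
                boot = _ward_linkage(values[:, idx])
                for c in _clades(boot, labels):
                    if c in counts:
                        counts[c] += 1
            dendro.support = {c: k / self.n_boot for c, k in counts.items()}
            dendro.n_boot = self.n_boot
            dendro.seed = self.random_state
        self.dendrogram_ = dendro
        return self


def ward_cluster(matrix: pd.DataFrame, axis: str = "rows") -> SupportedDendrogram:
    """Fit a Ward.D2 tree without support (thin wrapper)."""
    return WardClusterer(axis=axis).fit(matrix).dendrogram_


def bootstrap_support(
    matrix: pd.DataFrame,
    axis: str = "rows",
    n_boot: int = 10_000,
    seed: int | None = None,
) -> SupportedDendrogram:
    """Fit a Ward.D2 tree with bootstrap clade support (thin wrapper)."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    return WardClusterer(axis=axis, n_boot=n_boot, random_state=seed).fit(matrix).dendrogram_
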