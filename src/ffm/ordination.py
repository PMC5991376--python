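"""PCA ordination of trait space and trophic-profile space.

Covariance PCA of the (already standardized) trait matrix is equivalent to
correlation PCA of the raw traits; the TP matrix is ordinated as-is, since
tau values are already commensurate in [-1, 1]. Component signs are fixed
deterministically: each loading vector is flipped so that its
largest-magnitude entry is positive (PCA signs are otherwise arbitrary).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

class PCAOrdination(BaseEstimator):
    """Centered principal-component ordination with a fixed sign convention.

    Parameters
    ----------
    n_components : int or None
        Number of components to keep; None keeps all.

    Attributes
    ----------
    scores_ : DataFrame (rows x components) — coordinates of the fitted rows.
    loadings_ : DataFrame (variables x components) — eigenvector loadings.
    explained_fraction_ : ndarray — per-component fraction of total variance,
        non-increasing and summing to 1 over all components.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X: pd.DataFrame, y=None) -> "PCAOrdination":
        X = pd.DataFrame(X)
        if X.isna().any().any():
            raise ValueError("PCA input has missing cells")
        if X.shape[0] < 2 or X.shape[1] < 2:
            raise ValueError("PCA needs at least 2 rows and 2 columns")
        values = X.to_numpy(dtype=float)
        if np.allclose(values, values.mean(axis=0), atol=0):
            raise ValueError("PCA input has rank 0 (all rows identical)")

        pca = PCA(n_components=self.n_components, svd_solver="full")
        scores = pca.fit_transform(values)

        # deterministic orientation: largest-|loading| entry of each component > 0
        flip = np.ones(pca.components_.shape[0])
        for k, comp in enumerate(pca.components_):
            if comp[np.argmax(np.abs(comp))] < 0:
                flip[k] = -1.0
        comps = pca.components_ * flip[:, None]
        scores = scores * flip[None, :]

        names = [f"PC{k + 1}" for k in range(comps.shape[0])]
        self.scores_ = pd.DataFrame(scores, index=X.index, columns=names)
        self.loadings_ = pd.DataFrame(comps.T, index=X.columns, columns=names)
        self.explained_fraction_ = pca.explained_variance_ratio_.copy()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        cols = self.loadings_.index
        centered = pd.DataFrame(X)[cols].to_numpy(dtype=float) - pd.DataFrame(X)[
            cols
        ].to_numpy(dtype=float).mean(axis=0)
        return pd.DataFrame(
            centered @ self.loadings_.to_numpy(),
            index=pd.DataFrame(X).index,
            columns=self.loadings_.columns,
        )

    def explained_first_k(self, k: int) -> float:
        """Cumulative explained-variance fraction of the first ``k`` components."""
        if not 1 <= k <= len(self.explained_fraction_):
            raise ValueError(
                f"k must be in 1..{len(self.explained_fraction_)}, got {k}"
            )
        return float(self.explained_fraction_[:k].sum())


def pca(matrix: pd.DataFrame, n_components: int | None = None) -> PCAOrdination:
    """Fit a PCA ordination (thin wrapper over :class:`PCAOrdination`)."""
    return PCAOrdination(n_components=n_components).fit(matrix)


def explained_first_k(result: PCAOrdination, k: int) -> float:
    return result.explained_first_k(k)
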