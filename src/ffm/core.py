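"""Core of the food-fish model: standardization, optimum-type transforms and
Kendall-tau trophic profiles.

The model scores how well a fish's trophic morphology matches the "ideal"
morphology of a specialist on each aquatic food resource. For every food
type, a food-specialist profile (FSP) gives each trait an integer effect in
{-2, -1, 0, +1, +2}: the sign says whether a large value of the trait helps
or hinders exploiting that resource, the magnitude how strongly. Trait values
(across specimens) and FSP effects (across food types) are standardized to
z-scores so every variable carries equal weight, and each specimen's
standardized trait vector is rank-correlated (Kendall tau-b) with each food
type's standardized effect vector. The resulting vector of correlations —
one per food type, each in [-1, 1] — is the specimen's *trophic profile*
(TP): its relative capacity to utilize each resource.

A few traits are *optimum-type*: capacity peaks at an intermediate trait
value rather than increasing monotonically (e.g. relative body depth).
For those traits, wherever their effect on a food type is nonzero, the
specimen's z-score is replaced by the negated absolute deviation from the
optimum before correlating, so any departure from the optimum scores as a
penalty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FSPMatrix:
    """Food-specialist profiles: food types x traits integer effect matrix.

    ``effects`` is indexed by food type with trait abbreviations as columns;
    entries lie in {-2, -1, 0, +1, +2}. ``optimum_traits`` lists the traits
    scored as deviation-from-optimum rather than monotonically.
    """

    effects: pd.DataFrame
    optimum_traits: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        vals = self.effects.to_numpy()
        if not np.isin(vals, [-2, -1, 0, 1, 2]).all():
            raise ValueError("FSP effects must be integers in -2..+2")
        if len(self.effects) < 2:
            raise ValueError("FSP matrix needs at least 2 food types")
        if self.effects.index.duplicated().any():
            raise ValueError("duplicate food types in FSP matrix")
        unknown = self.optimum_traits - set(self.effects.columns)
        if unknown:
            raise ValueError(f"optimum traits not in FSP trait set: {sorted(unknown)}")

    @property
    def food_types(self) -> list[str]:
        return list(self.effects.index)

    @property
    def trait_abbreviations(self) -> list[str]:
        return list(self.effects.columns)


class ColumnStandardizer(BaseEstimator, TransformerMixin):
    """Column-wise z-scoring: subtract the mean, divide by the SD.

    Applied to trait matrices (variables = traits, standardized across
    specimens) and to FSP effect matrices (variables = traits, standardized
    across food types) alike, so every variable ends with mean 0 and SD 1.

    Parameters
    ----------
    ddof : int
        Degrees-of-freedom correction for the SD; 1 (sample SD) by default.
    zero_variance : {"error", "drop"}
        What to do with constant columns: raise (default) or drop them
        (dropped columns are recorded in ``dropped_columns_`` and logged).
    """

    def __init__(self, ddof: int = 1, zero_variance: str = "error"):
        self.ddof = ddof
        self.zero_variance = zero_variance

    def fit(self, X: pd.DataFrame, y=None) -> "ColumnStandardizer":
        if len(X) < 2:
            raise ValueError("standardization needs at least 2 rows")
        if self.zero_variance not in ("error", "drop"):
            raise ValueError(f"unknown zero_variance policy {self.zero_variance!r}")
        X = pd.DataFrame(X)
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=self.ddof)
        constant = sd[(sd == 0) | sd.isna()].index.tolist()
        if constant and self.zero_variance == "error":
            raise ValueError(f"zero-variance column(s): {constant}")
        if constant:
            logger.warning("dropping zero-variance column(s): %s", constant)
        self.dropped_columns_ = constant
        self.columns_ = [c for c in X.columns if c not in constant]
        self.mean_ = mean[self.columns_]
        self.scale_ = sd[self.columns_]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)[self.columns_]
        return (X - self.mean_) / self.scale_


def standardize(
    matrix: pd.DataFrame, ddof: int = 1, zero_variance: str = "error"
) -> pd.DataFrame:
    """Z-score each column of ``matrix`` (thin wrapper over ColumnStandardizer)."""
    return ColumnStandardizer(ddof=ddof, zero_variance=zero_variance).fit_transform(matrix)


def kendall_tau(x, y) -> float:
    """Kendall's tau-b (tie-corrected) rank correlation of two paired vectors.

    Raises if the vectors differ in length, are shorter than 2, or if either
    is constant (tau is undefined there; constant variables must have been
    removed upstream by the zero-variance policy).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("kendall_tau: x and y must be 1-d and of equal length")
    if len(x) < 2:
        raise ValueError("kendall_tau: need at least 2 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("kendall_tau: tau is undefined for a constant vector")
    res = stats.kendalltau(x, y, variant="b")
    return float(res.statistic)


def apply_optimum_transform(
    z_traits: pd.Series,
    fsp: FSPMatrix,
    food_type: str,
    optima: dict[str, float] | None = None,
    missing_ok: frozenset[str] | set[str] = frozenset(),
) -> pd.Series:
    """Score optimum-type traits as negated deviation from their optimum.

    For each trait in ``fsp.optimum_traits`` whose effect on ``food_type`` is
    nonzero, the specimen's z-score z is replaced by ``-|z - z_opt|``; all
    other entries pass through. The default optimum is z_opt = 0, the
    standardized sample mean. ``missing_ok`` names traits legitimately absent
    from the vector (dropped by the zero-variance policy); any other absent
    optimum trait is an error.
    """
    optima = optima or {}
    out = z_traits.copy()
    row = fsp.effects.loc[food_type]
    for trait in fsp.optimum_traits:
        if trait not in z_traits.index:
            if trait in missing_ok:
                continue
            raise ValueError(f"optimum trait {trait!r} absent from trait vector")
        if row[trait] != 0:
            z_opt = optima.get(trait, 0.0)
            out[trait] = -abs(out[trait] - z_opt)
    return out


class TrophicProfiler(BaseEstimator, TransformerMixin):
    """Turn standardized trait vectors into trophic profiles.

    ``fit`` aligns the FSP to the trait matrix's columns and standardizes
    each FSP trait column across food types; ``transform`` computes, for each
    specimen, the Kendall tau-b between its (optimum-transformed)
    standardized trait vector and each food type's standardized effect row.

    Parameters
    ----------
    fsp : FSPMatrix
        Integer effect matrix with optimum-trait declarations.
    optima : dict, optional
        Per-trait optimum z-values for optimum-type traits (default 0.0).
    ddof : int
        SD convention used when standardizing FSP effects.
    zero_variance : {"error", "drop"}
        Policy for FSP trait columns constant across food types.

    Attributes
    ----------
    fsp_z_ : DataFrame
        Standardized effect matrix restricted to the retained traits.
    retained_traits_ : list of str
        Traits common to the trait matrix and the standardized FSP.
    """

    def __init__(
        self,
        fsp: FSPMatrix,
        optima: dict[str, float] | None = None,
        ddof: int = 1,
        zero_variance: str = "error",
    ):
        self.fsp = fsp
        self.optima = optima
        self.ddof = ddof
        self.zero_variance = zero_variance

    def fit(self, X: pd.DataFrame, y=None) -> "TrophicProfiler":
        traits = list(X.columns)
        fsp_traits = set(self.fsp.trait_abbreviations)
        missing = set(traits) - fsp_traits
        if missing:
            raise ValueError(f"traits absent from FSP matrix: {sorted(missing)}")
        effects = self.fsp.effects[traits]
        std = ColumnStandardizer(ddof=self.ddof, zero_variance=self.zero_variance)
        self.fsp_z_ = std.fit_transform(effects)
        self.retained_traits_ = list(self.fsp_z_.columns)
        self.dropped_traits_ = frozenset(self.fsp.trait_abbreviations) - set(
            self.retained_traits_
        )
        for food, row in self.fsp_z_.iterrows():
            if np.ptp(row.to_numpy()) == 0:
                raise ValueError(f"standardized FSP row for {food!r} is constant")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Return the TP matrix: specimens x food types, tau values in [-1, 1]."""
        Z = X[self.retained_traits_]
        out = pd.DataFrame(
            index=Z.index, columns=self.fsp.food_types, dtype=float
        )
        for food in self.fsp.food_types:
            fz = self.fsp_z_.loc[food]
            for sid, z in Z.iterrows():
                v = apply_optimum_transform(
                    z, self.fsp, food, self.optima, missing_ok=self.dropped_traits_
                )
                out.at[sid, food] = kendall_tau(v[self.retained_traits_], fz)
        out.index.name = "specimen_id"
        return out


def compute_trophic_profile(
    specimen_z: pd.Series,
    fsp: FSPMatrix,
    optima: dict[str, float] | None = None,
    ddof: int = 1,
    zero_variance: str = "error",
) -> pd.Series:
    """Trophic profile of a single standardized trait vector (thin wrapper)."""
    Z = specimen_z.to_frame().T
    profiler = TrophicProfiler(
        fsp, optima=optima, ddof=ddof, zero_variance=zero_variance
    ).fit(Z)
    return profiler.transform(Z).iloc[0]


def mean_trophic_profiles(tp: pd.DataFrame, species: pd.Series) -> pd.DataFrame:
    """Arithmetic mean TP per species, with specimen counts.

    ``species`` maps specimen id -> species name; every specimen in ``tp``
    must be mapped. Returns a DataFrame indexed by species (first-appearance
    order) with the food-type columns of ``tp`` plus an ``n`` column.
    """
    sp = species.reindex(tp.index)
    if sp.isna().any():
        missing = list(tp.index[sp.isna()])
        raise ValueError(f"specimens without a species mapping: {missing}")
    grouped = tp.groupby(sp, sort=False)
    means = grouped.mean()
    means["n"] = grouped.size()
    means.index.name = "species"
    return means
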