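"""Specimen records: completeness filtering, size scaling and species summaries.

Raw trait values are measured on fish of different sizes, so metric traits
carry a strong isometric size signal. Scaling divides lengths by standard
length (SL) and areas by SL^2, leaving ratios, angles and binary traits
untouched; the result is a dense specimens x traits matrix on a size-free
scale, ready for standardization.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .schema import DEFAULT_SCHEMA, TraitSchema

logger = logging.getLogger(__name__)


@dataclass
class SpecimenRecord:
    """One measured fish: identity, provenance and raw trait values.

    ``raw_traits`` maps trait abbreviation to the raw measurement; a missing
    measurement is an *absent key* (never 0, which is a legal binary value).
    """

    specimen_id: str
    species: str
    status: str  # "native" or "alien"
    standard_length: float  # mm
    raw_traits: dict[str, float] = field(default_factory=dict)

    def is_complete(self, schema: TraitSchema) -> bool:
        if not np.isfinite(self.standard_length) or self.standard_length <= 0:
            return False
        return all(a in self.raw_traits for a in schema.abbreviations)


class TraitScaler(BaseEstimator, TransformerMixin):
    """Remove isometric size effects from raw trait measurements.

    Per the schema's scaling rules: metric lengths are divided by the
    specimen's SL, areas by SL^2, and ratio/angle/binary traits pass through.
    The transform is stateless; ``fit`` only validates the schema.

    Parameters
    ----------
    schema : TraitSchema
        Trait catalogue defining column order and scaling rules.
    """

    def __init__(self, schema: TraitSchema = DEFAULT_SCHEMA):
        self.schema = schema

    def fit(self, X: list[SpecimenRecord], y=None) -> "TraitScaler":
        self.n_traits_ = len(self.schema)
        return self

    def transform(self, X: list[SpecimenRecord]) -> pd.DataFrame:
        """Return the scaled specimens x traits matrix.

        Raises
        ------
        ValueError
            If a specimen has SL <= 0 or is missing a schema trait
            (run :func:`filter_complete` first).
        """
        rows = {}
        for rec in X:
            if not np.isfinite(rec.standard_length) or rec.standard_length <= 0:
                raise ValueError(
                    f"specimen {rec.specimen_id!r}: standard length must be > 0, "
                    f"got {rec.standard_length}"
                )
            sl = rec.standard_length
            row = {}
            for trait in self.schema.traits:
                a = trait.abbreviation
                if a not in rec.raw_traits:
                    raise ValueError(
                        f"specimen {rec.specimen_id!r} is missing trait {a!r}; "
                        "apply filter_complete before scaling"
                    )
                v = rec.raw_traits[a]
                if trait.scaling == "SL":
                    row[a] = v / sl
                elif trait.scaling == "SL2":
                    row[a] = v / sl**2
                else:
                    row[a] = v
            rows[rec.specimen_id] = row
        out = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
        out = out.reindex(columns=self.schema.abbreviations)
        out.index.name = "specimen_id"
        out.attrs["scaled"] = True
        return out


def filter_complete(
    records: list[SpecimenRecord], schema: TraitSchema = DEFAULT_SCHEMA
) -> list[SpecimenRecord]:
    """Keep only specimens with a valid SL and a value for every schema trait.

    Removal counts are logged per species; filtering is idempotent.
    """
    kept = [r for r in records if r.is_complete(schema)]
    removed = Counter(r.species for r in records if not r.is_complete(schema))
    for species, n in sorted(removed.items()):
        logger.warning("filter_complete: removed %d incomplete specimen(s) of %s", n, species)
    if records and not kept:
        logger.warning("filter_complete: no complete specimens remain")
    return kept


def scale_traits(
    records: list[SpecimenRecord], schema: TraitSchema = DEFAULT_SCHEMA
) -> pd.DataFrame:
    """Size-scale complete records into a specimens x traits matrix (thin wrapper)."""
    return TraitScaler(schema).fit(records).transform(records)


def summarize_species(
    records: list[SpecimenRecord], ddof: int = 1, single_sd: float | None = 0.0
) -> pd.DataFrame:
    """Per-species specimen counts and standard-length statistics.

    Parameters
    ----------
    records : list of SpecimenRecord
    ddof : int
        Delta degrees of freedom for the SD (1 = sample SD, the default).
    single_sd : float or None
        Value reported for the SD of a single-specimen species (0.0 or NaN).

    Returns
    -------
    DataFrame with columns species, status, n, sl_min, sl_max, sl_mean, sl_sd,
    one row per species in first-appearance order.
    """
    if not records:
        raise ValueError("summarize_species: no records")
    order: list[str] = []
    by_species: dict[str, list[SpecimenRecord]] = {}
    for r in records:
        if r.species not in by_species:
            by_species[r.species] = []
            order.append(r.species)
        by_species[r.species].append(r)

    rows = []
    for sp in order:
        group = by_species[sp]
        sl = np.array([r.standard_length for r in group], dtype=float)
        if len(sl) > ddof:
            sd = float(np.std(sl, ddof=ddof))
        else:
            sd = np.nan if single_sd is None else single_sd
        rows.append(
            {
                "species": sp,
                "status": group[0].status,
                "n": len(group),
                "sl_min": float(sl.min()),
                "sl_max": float(sl.max()),
                "sl_mean": float(sl.mean()),
                "sl_sd": sd,
            }
        )
    return pd.DataFrame(rows)
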