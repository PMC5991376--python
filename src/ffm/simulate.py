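"""Synthetic specimen tables and food-specialist profiles.

Generates data with the statistical structure the analysis assumes —
per-species multivariate trait distributions on the size-free (scaled) scale,
multiplied back to raw measurements so that size scaling inverts the
construction, plus random integer FSP matrices — so every pipeline stage is
testable without any external download.

The default nine-species fixture mirrors the structure of a benthic-fish
community study: species-specific standard-length means/SDs and specimen
counts (6-14 per species, 85 in total), three morphological species groups
(a barbelled small-gape group, a large-gape bullhead-like group, a deep-body
goby group) and one morphologically average species. The shipped default FSP
matrix is a SYNTHETIC stand-in: hand-written, ecologically plausible effect
values for ten aquatic food resources; it is a fixture, not an estimate of
any real profile set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ColumnStandardizer, FSPMatrix
from .schema import DEFAULT_OPTIMUM_TRAITS, DEFAULT_SCHEMA, TraitSchema
from .trait_data import SpecimenRecord


@dataclass
class SpeciesSpec:
    """Generative description of one species' specimens.

    Continuous trait means/SDs are on the *scaled* (size-free) scale; raw
    records are produced by multiplying back by SL (lengths) or SL^2 (areas).
    ``correlation`` is an equicorrelation level applied to the continuous
    traits within a specimen.
    """

    species: str
    status: str
    n: int
    sl_mean: float
    sl_sd: float
    trait_means: dict[str, float] = field(default_factory=dict)
    trait_sds: dict[str, float] = field(default_factory=dict)
    binary_probs: dict[str, float] = field(default_factory=dict)
    correlation: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"{self.species}: n must be >= 1")
        if self.sl_sd < 0 or any(s < 0 for s in self.trait_sds.values()):
            raise ValueError(f"{self.species}: SDs must be >= 0")
        if not all(0.0 <= p <= 1.0 for p in self.binary_probs.values()):
            raise ValueError(f"{self.species}: binary probabilities must be in [0, 1]")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError(f"{self.species}: correlation must be in [0, 1)")


# --------------------------------------------------------------------------
# default fixture: nine species, 85 specimens
# --------------------------------------------------------------------------

#: per-species SL statistics (status, n, SL min, max, mean, SD in mm) of the
#: nine-species reference community
SPECIES_SL_STATS: dict[str, tuple[str, int, float, float, float, float]] = {
    "Barbatula barbatula": ("native", 10, 41.1, 75.2, 64.3, 12.2),
    "Cottus perifretum": ("native", 8, 40.5, 69.6, 54.4, 8.9),
    "Cottus rhenanus": ("native", 9, 43.8, 64.6, 55.2, 5.5),
    "Gobio gobio": ("native", 6, 92.7, 115.7, 106.4, 10.4),
    "Neogobius fluviatilis": ("alien", 10, 51.4, 118.3, 72.4, 19.6),
    "Neogobius melanostomus": ("alien", 13, 46.5, 99.7, 69.0, 21.6),
    "Ponticola kessleri": ("alien", 9, 68.2, 95.0, 80.0, 8.0),
    "Proterorhinus semilunaris": ("alien", 10, 40.0, 68.3, 54.5, 8.3),
    "Romanogobio belingi": ("alien", 10, 63.0, 105.6, 85.5, 15.8),
}

#: baseline scaled-trait means for a generic benthic fish
_BASE_MEANS: dict[str, float] = {
    "BD": 0.22, "CPD": 0.10, "ED": 0.06, "OGAr": 0.012, "GiRL/GiRD": 1.0,
    "GiRD": 0.010, "GiRL": 0.010, "GuL": 0.90, "HL": 0.26, "HyL": 0.12,
    "Ljin/Ljout": 0.35, "LJL": 0.10, "OpAr": 0.018, "OGAx": 45.0,
    "PLOW": 0.035, "ProtL": 0.020, "OGAr/BAr": 0.45, "HyL/LJSL": 0.80,
    "POrL/OpD": 1.30,
}

#: per-species multiplicative offsets from the baseline (unlisted traits: 1.0)
_SPECIES_SHIFTS: dict[str, dict[str, float]] = {
    # barbelled, small-gape, small-operculum group
    "Barbatula barbatula": {"OGAr": 0.60, "OpAr": 0.70, "GuL": 0.85, "BD": 0.75,
                            "OGAx": 0.65, "PLOW": 1.2},
    "Gobio gobio": {"OGAr": 0.60, "OpAr": 0.70, "GuL": 1.30, "ProtL": 1.5,
                    "OGAx": 0.75, "PLOW": 1.3},
    "Romanogobio belingi": {"OGAr": 0.65, "OpAr": 0.75, "GuL": 1.25, "ProtL": 1.4,
                            "OGAx": 0.75, "PLOW": 1.25},
    # large-gape, large-head, wide-raker group
    "Cottus perifretum": {"OGAr": 1.80, "HL": 1.25, "GiRD": 1.50, "GuL": 0.60,
                          "OGAr/BAr": 1.4, "LJL": 1.3},
    "Cottus rhenanus": {"OGAr": 1.70, "HL": 1.20, "GiRD": 1.45, "GuL": 0.60,
                        "OGAr/BAr": 1.35, "LJL": 1.25},
    "Ponticola kessleri": {"OGAr": 1.90, "HL": 1.30, "GiRD": 1.60, "GuL": 0.65,
                           "HyL": 1.2, "OGAr/BAr": 1.45, "LJL": 1.35},
    # deep-bodied, long-gut goby group
    "Proterorhinus semilunaris": {"BD": 1.30, "GuL": 1.20, "ED": 1.10},
    "Neogobius melanostomus": {"BD": 1.35, "GuL": 1.25, "CPD": 1.1},
    # morphologically average
    "Neogobius fluviatilis": {},
}

#: per-species presence probabilities for the binary traits
_BINARY_PROBS: dict[str, dict[str, float]] = {
    "Barbatula barbatula": {"Ba": 1.0, "TOT": 0.0, "TPT2": 0.0},
    "Gobio gobio": {"Ba": 1.0, "TOT": 0.0, "TPT2": 1.0},
    "Romanogobio belingi": {"Ba": 1.0, "TOT": 0.0, "TPT2": 1.0},
    "Cottus perifretum": {"Ba": 0.0, "TOT": 1.0, "TPT2": 0.0},
    "Cottus rhenanus": {"Ba": 0.0, "TOT": 1.0, "TPT2": 0.0},
    "Ponticola kessleri": {"Ba": 0.0, "TOT": 1.0, "TPT2": 0.0},
    "Proterorhinus semilunaris": {"Ba": 0.0, "TOT": 1.0, "TPT2": 0.0},
    "Neogobius melanostomus": {"Ba": 0.0, "TOT": 1.0, "TPT2": 0.0},
    "Neogobius fluviatilis": {"Ba": 0.0, "TOT": 1.0, "TPT2": 0.0},
}

#: relative within-species SD of continuous traits (fraction of the mean)
_CV = 0.08


def default_species_specs(schema: TraitSchema = DEFAULT_SCHEMA) -> list[SpeciesSpec]:
    """The nine-species, 85-specimen default fixture."""
    binary = set(schema.binary_traits())
    specs = []
    for species, (status, n, _, _, sl_mean, sl_sd) in SPECIES_SL_STATS.items():
        shifts = _SPECIES_SHIFTS[species]
        means, sds = {}, {}
        for a in schema.abbreviations:
            if a in binary:
                continue
            m = _BASE_MEANS[a] * shifts.get(a, 1.0)
            means[a] = m
            sds[a] = _CV * m
        specs.append(
            SpeciesSpec(
                species=species,
                status=status,
                n=n,
                sl_mean=sl_mean,
                sl_sd=sl_sd,
                trait_means=means,
                trait_sds=sds,
                binary_probs={a: _BINARY_PROBS[species][a] for a in binary},
                correlation=0.3,
            )
        )
    return specs


def generate_specimens(
    specs: list[SpeciesSpec],
    schema: TraitSchema = DEFAULT_SCHEMA,
    seed: int | None = None,
) -> list[SpecimenRecord]:
    """Draw raw specimen records from per-species distributions.

    SL ~ Normal(sl_mean, sl_sd) truncated at > 0; continuous traits are drawn
    (equicorrelated) Normal on the scaled scale and multiplied back by SL or
    SL^2; binary traits are Bernoulli. Bit-reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    binary = set(schema.binary_traits())
    records: list[SpecimenRecord] = []
    for spec in specs:
        cont = [a for a in schema.abbreviations if a not in binary]
        unknown = (set(spec.trait_means) | set(spec.trait_sds) | set(spec.binary_probs)) - set(
            schema.abbreviations
        )
        if unknown:
            raise ValueError(f"{spec.species}: unknown trait(s) in spec: {sorted(unknown)}")
        mu = np.array([spec.trait_means.get(a, 0.0) for a in cont])
        sd = np.array([spec.trait_sds.get(a, 0.0) for a in cont])
        rho = spec.correlation
        for i in range(spec.n):
            sl = 0.0
            while sl <= 0:
                sl = rng.normal(spec.sl_mean, spec.sl_sd) if spec.sl_sd > 0 else spec.sl_mean
            # equicorrelated unit normals: shared factor + independent residual
            z = np.sqrt(rho) * rng.normal() + np.sqrt(1 - rho) * rng.normal(size=len(cont))
            scaled = mu + sd * z
            scaled = np.maximum(scaled, 0.0)  # raw metric values must be >= 0
            traits: dict[str, float] = {}
            for a, v in zip(cont, scaled):
                rule = schema[a].scaling
                if rule == "SL":
                    traits[a] = v * sl
                elif rule == "SL2":
                    traits[a] = v * sl**2
                else:
                    traits[a] = v
            for a in schema.abbreviations:
                if a in binary:
                    p = spec.binary_probs.get(a, 0.0)
                    traits[a] = float(rng.random() < p)
            records.append(
                SpecimenRecord(
                    specimen_id=f"{spec.species.replace(' ', '_')}_{i + 1}",
                    species=spec.species,
                    status=spec.status,
                    standard_length=float(sl),
                    raw_traits=traits,
                )
            )
    return records


def generate_fsp(
    n_foods: int,
    schema: TraitSchema = DEFAULT_SCHEMA,
    seed: int | None = None,
    sparsity: float = 0.35,
    food_names: list[str] | None = None,
) -> FSPMatrix:
    """Random integer FSP matrix with effects in {-2..+2}.

    Each cell is 0 with probability ``sparsity``, otherwise uniform on
    {-2, -1, +1, +2}. The draw is rejected and repeated until no food row is
    all-zero and no trait column is constant (constant columns would be
    undefined under standardization); an infeasible sparsity raises.
    """
    if n_foods < 2:
        raise ValueError("need at least 2 food types")
    if not 0.0 <= sparsity <= 1.0:
        raise ValueError("sparsity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    names = food_names or [f"food_{i + 1}" for i in range(n_foods)]
    if len(names) != n_foods:
        raise ValueError("food_names length must equal n_foods")
    traits = schema.abbreviations
    nonzero = np.array([-2, -1, 1, 2])
    for _ in range(200):
        zeros = rng.random((n_foods, len(traits))) < sparsity
        vals = rng.choice(nonzero, size=(n_foods, len(traits)))
        m = np.where(zeros, 0, vals)
        row_ok = (m != 0).any(axis=1).all()
        col_ok = all(len(np.unique(m[:, j])) > 1 for j in range(m.shape[1]))
        if row_ok and col_ok:
            effects = pd.DataFrame(m, index=pd.Index(names, name="food_type"), columns=traits)
            return FSPMatrix(effects=effects)
    raise ValueError(f"infeasible sparsity {sparsity}: cannot satisfy row/column constraints")


#: the ten default aquatic food resources
DEFAULT_FOOD_TYPES = [
    "benthic insect larvae", "mollusks", "detritus", "crustaceans",
    "sessile algae", "phytoplankton", "zooplankton", "fish (ambush)",
    "fish (pursuit)", "insects",
]

# Hand-written SYNTHETIC effect values (food type -> nonzero trait effects).
# Plausible functional-morphology reasoning only; a fixture, not data.
_DEFAULT_FSP_EFFECTS: dict[str, dict[str, int]] = {
    "benthic insect larvae": {"Ba": 2, "ED": -1, "OGAx": -1, "TPT2": 1, "PLOW": 1,
                              "ProtL": 2, "HyL": 1, "Ljin/Ljout": 1, "HyL/LJSL": 1,
                              "GiRD": -1},
    "mollusks": {"Ba": 1, "ED": -1, "OGAr": -1, "Ljin/Ljout": 2, "TPT2": 2,
                 "PLOW": 2, "ProtL": 1, "HyL/LJSL": -1, "GuL": 1},
    "detritus": {"Ba": 1, "ED": -2, "OGAr": -1, "GuL": 2, "OGAx": -2, "TOT": -2,
                 "PLOW": 1, "ProtL": 1, "OpAr": -1, "POrL/OpD": -1},
    "crustaceans": {"TOT": 1, "OGAr": 1, "Ljin/Ljout": 1, "HL": 1, "ED": 1,
                    "TPT2": 1, "HyL": 1, "GiRD": 1},
    "sessile algae": {"GuL": 2, "TOT": -1, "OGAx": -2, "Ba": 1, "PLOW": 1,
                      "OGAr": -2, "ED": -1, "TPT2": 1, "ProtL": 1, "Ljin/Ljout": 1},
    "phytoplankton": {"GiRL": 2, "GiRL/GiRD": 2, "GiRD": -2, "GuL": 1, "OGAr": -1,
                      "ED": -1, "TOT": -1, "BD": 1},
    "zooplankton": {"GiRL": 1, "GiRL/GiRD": 1, "GiRD": -1, "ED": 1, "OGAx": 1,
                    "ProtL": 1, "OGAr": -1, "HyL/LJSL": 1, "OpAr": 1},
    "fish (ambush)": {"OGAr": 2, "HL": 2, "GiRD": 2, "TOT": 2, "GuL": -2, "HyL": 2,
                      "OGAx": 1, "BD": -1, "HyL/LJSL": 2, "GiRL": -1, "ED": 1,
                      "LJL": 2, "OGAr/BAr": 2, "OpAr": 1, "POrL/OpD": 1},
    "fish (pursuit)": {"OGAr": 2, "BD": -2, "CPD": -1, "TOT": 2, "GuL": -2, "HL": 1,
                       "LJL": 1, "ED": 2, "OGAr/BAr": 1, "HyL/LJSL": 1, "GiRD": 1},
    "insects": {"OGAx": 2, "ED": 2, "ProtL": 1, "OGAr": 1, "TOT": 1, "GuL": -1,
                "BD": -1, "LJL": 1},
}


def default_fsp(schema: TraitSchema = DEFAULT_SCHEMA) -> FSPMatrix:
    """The shipped synthetic FSP fixture: ten food types x 22 traits.

    Effects are hand-written plausible values (e.g. pursuit piscivores: large
    gape, large eye, short gut, shallow body); optimum-type traits are
    velocity suction capacity, relative gape area and body depth.
    """
    rows = []
    for food in DEFAULT_FOOD_TYPES:
        eff = _DEFAULT_FSP_EFFECTS[food]
        rows.append([eff.get(a, 0) for a in schema.abbreviations])
    effects = pd.DataFrame(
        rows, index=pd.Index(DEFAULT_FOOD_TYPES, name="food_type"),
        columns=schema.abbreviations, dtype=int,
    )
    return FSPMatrix(effects=effects, optimum_traits=DEFAULT_OPTIMUM_TRAITS)


def plant_specialist(
    fsp: FSPMatrix,
    food_type: str,
    noise_sd: float = 0.0,
    seed: int | None = None,
    ddof: int = 1,
) -> pd.Series:
    """Standardized trait vector of a synthetic perfect specialist.

    The vector is a strictly increasing map (z + z^3/4) of ``food_type``'s
    standardized effect row, plus Normal(0, noise_sd) jitter — at zero noise
    and tie-free effects its trophic-profile entry for ``food_type`` is
    exactly 1. Returned as a Series on the standardized scale (standardization
    is sample-dependent, so no raw single record could carry these values).
    """
    if food_type not in fsp.food_types:
        raise ValueError(f"unknown food type {food_type!r}")
    rng = np.random.default_rng(seed)
    fz = ColumnStandardizer(ddof=ddof).fit_transform(fsp.effects).loc[food_type]
    z = fz + 0.25 * fz**3
    if noise_sd > 0:
        z = z + rng.normal(0.0, noise_sd, size=len(z))
    z.name = f"specialist[{food_type}]"
    return z


def planted_group_matrix(
    n_groups: int = 2,
    leaves_per_group: int = 3,
    n_features: int = 10,
    spread: float = 0.05,
    separation: float = 5.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, list[frozenset[str]]]:
    """Mean-TP-like matrix with planted groups, for clustering recovery tests.

    Group centers are offset by ``separation * spread`` in every feature;
    rows scatter Normal(0, spread) around their center. Returns the matrix
    and the planted groups as leaf-label sets.
    """
    rng = np.random.default_rng(seed)
    rows, labels, groups = [], [], []
    for g in range(n_groups):
        center = np.full(n_features, g * separation * spread)
        members = []
        for i in range(leaves_per_group):
            rows.append(center + rng.normal(0.0, spread, size=n_features))
            label = f"group{g + 1}_sp{i + 1}"
            labels.append(label)
            members.append(label)
        groups.append(frozenset(members))
    matrix = pd.DataFrame(
        rows, index=labels, columns=[f"food_{j + 1}" for j in range(n_features)]
    )
    return matrix, groups


def exact_moment_lengths(
    n: int, lo: float, hi: float, mean: float, sd: float
) -> np.ndarray:
    """Construct ``n`` lengths with exactly the given min, max, mean and
    sample SD (ddof=1).

    The two extremes are placed at ``lo`` and ``hi``; the interior points sit
    symmetrically at c - d and c + d (plus one at c when the interior count
    is odd), with c and d solved from the mean and SD constraints. Raises if
    no such configuration exists within [lo, hi]. Used to materialize a
    specimen table from printed summary statistics.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if not (lo < hi and lo <= mean <= hi and sd > 0):
        raise ValueError("inconsistent summary statistics")
    k = n - 2
    t = np.array([1.0, -1.0] * (k // 2) + ([0.0] if k % 2 else []))
    c = (n * mean - lo - hi) / k
    ss = (n - 1) * sd**2 - (lo - mean) ** 2 - (hi - mean) ** 2 - k * (c - mean) ** 2
    if ss < 0:
        raise ValueError("summary statistics are infeasible (SD too small)")
    d = np.sqrt(ss / (t**2).sum())
    values = np.concatenate([[lo, hi], c + d * t])
    if values.min() < lo - 1e-9 or values.max() > hi + 1e-9:
        raise ValueError("summary statistics are infeasible (interior exceeds range)")
    return np.sort(values)
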