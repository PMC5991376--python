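"""Trait schema: the declarative catalogue of functional feeding traits.

Each trait is one of five kinds, and its kind fixes how it is scaled to
remove body-size (isometric) effects:

* ``metric-length`` — a linear measurement in mm, divided by standard length (SL);
* ``metric-area``   — a surface area in mm^2, divided by SL^2;
* ``ratio``         — a dimensionless ratio of two measurements, not scaled;
* ``angle``         — an orientation in degrees, not scaled;
* ``binary``        — presence/absence coded 0/1, not scaled.

The default schema holds the 22 traits of the benthic-fish feeding-trait set
(barbels through opercular volume capacity), keyed by their conventional
abbreviations (BD, OGAr, HyL/LJSL, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field

TRAIT_KINDS = ("metric-length", "metric-area", "ratio", "angle", "binary")

#: scaling rule implied by each trait kind
KIND_SCALING = {
    "metric-length": "SL",
    "metric-area": "SL2",
    "ratio": "none",
    "angle": "none",
    "binary": "none",
}


@dataclass(frozen=True)
class TraitDef:
    """Definition of a single trait: name, abbreviation, kind and scaling rule."""

    name: str
    abbreviation: str
    kind: str
    scaling: str = ""

    def __post_init__(self) -> None:
        if self.kind not in TRAIT_KINDS:
            raise ValueError(f"unknown trait kind {self.kind!r} for {self.abbreviation}")
        expected = KIND_SCALING[self.kind]
        if self.scaling == "":
            object.__setattr__(self, "scaling", expected)
        elif self.scaling != expected:
            raise ValueError(
                f"trait {self.abbreviation}: kind {self.kind!r} requires scaling "
                f"{expected!r}, got {self.scaling!r}"
            )


@dataclass(frozen=True)
class TraitSchema:
    """Ordered collection of :class:`TraitDef`, unique by abbreviation."""

    traits: tuple[TraitDef, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        abbrevs = [t.abbreviation for t in self.traits]
        if len(set(abbrevs)) != len(abbrevs):
            dupes = sorted({a for a in abbrevs if abbrevs.count(a) > 1})
            raise ValueError(f"duplicate trait abbreviations: {dupes}")

    @property
    def abbreviations(self) -> list[str]:
        return [t.abbreviation for t in self.traits]

    def __len__(self) -> int:
        return len(self.traits)

    def __contains__(self, abbreviation: str) -> bool:
        return any(t.abbreviation == abbreviation for t in self.traits)

    def __getitem__(self, abbreviation: str) -> TraitDef:
        for t in self.traits:
            if t.abbreviation == abbreviation:
                return t
        raise KeyError(abbreviation)

    def binary_traits(self) -> list[str]:
        return [t.abbreviation for t in self.traits if t.kind == "binary"]


def _t(name: str, abbrev: str, kind: str) -> TraitDef:
    return TraitDef(name=name, abbreviation=abbrev, kind=kind)


#: The 22-trait default schema (alphabetical by trait name, as conventionally tabled).
DEFAULT_SCHEMA = TraitSchema(
    traits=(
        _t("Barbels (presence/absence)", "Ba", "binary"),
        _t("Body depth", "BD", "metric-length"),
        _t("Caudal peduncle depth", "CPD", "metric-length"),
        _t("Eye diameter", "ED", "metric-length"),
        _t("Gape size (oral gape area)", "OGAr", "metric-area"),
        _t("Gill arch resistance", "GiRL/GiRD", "ratio"),
        _t("Gill raker distance", "GiRD", "metric-length"),
        _t("Gill raker length", "GiRL", "metric-length"),
        _t("Gut length", "GuL", "metric-length"),
        _t("Head length", "HL", "metric-length"),
        _t("Hyoid length", "HyL", "metric-length"),
        _t("Lower jaw closing force efficiency", "Ljin/Ljout", "ratio"),
        _t("Lower jaw length", "LJL", "metric-length"),
        _t("Operculum area", "OpAr", "metric-area"),
        _t("Oral gape axis", "OGAx", "angle"),
        _t("Oral teeth presence", "TOT", "binary"),
        _t("Pharyngeal molariform teeth presence", "TPT2", "binary"),
        _t("Postlingual organ width", "PLOW", "metric-length"),
        _t("Protrusion length", "ProtL", "metric-length"),
        _t("Relative gape area", "OGAr/BAr", "ratio"),
        _t("Velocity suction capacity", "HyL/LJSL", "ratio"),
        _t("Volume capacity operculum", "POrL/OpD", "ratio"),
    )
)

#: Optimum-type traits: capacity peaks at an intermediate value, so deviation
#: from the optimum is scored negatively (see ffm.core.apply_optimum_transform).
DEFAULT_OPTIMUM_TRAITS = frozenset({"HyL/LJSL", "OGAr/BAr", "BD"})
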