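"""End-to-end pipeline: measurements + FSP in, tables/trees/report out.

Stages: load -> completeness filter -> size scaling -> standardization ->
trophic profiles -> mean TPs per species -> PCA of trait space and TP space
-> Ward clustering (by species and by food type) with bootstrap support.
All numeric outputs are written at full precision; the JSON run report
records counts, explained variances, support values, seeds and versions, and
together with the config fully determines reproduction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cluster import WardClusterer
from .core import ColumnStandardizer, FSPMatrix, TrophicProfiler, mean_trophic_profiles
from .io import (
    load_measurements,
    read_fsp,
    write_species_summary,
    write_trophic_profiles,
)
from .ordination import PCAOrdination
from .schema import DEFAULT_OPTIMUM_TRAITS, DEFAULT_SCHEMA, TraitSchema
from .trait_data import SpecimenRecord, filter_complete, scale_traits, summarize_species

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed to run (and re-run) the analysis."""

    measurements: str
    fsp: str
    outdir: str
    sheet: int | str = 0
    aliases: dict[str, str] = field(default_factory=dict)
    optimum_traits: list[str] = field(default_factory=lambda: sorted(DEFAULT_OPTIMUM_TRAITS))
    optima: dict[str, float] = field(default_factory=dict)
    ddof: int = 1
    zero_variance: str = "error"
    pca_components: int = 2
    n_boot: int = 10_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _fit_stages(
    records: list[SpecimenRecord],
    fsp: FSPMatrix,
    schema: TraitSchema,
    config: PipelineConfig,
):
    """Shared numeric core: scaled matrix -> Z, TP, mean TP, PCAs, trees."""
    scaled = scale_traits(records, schema)
    std = ColumnStandardizer(ddof=config.ddof, zero_variance=config.zero_variance)
    z_traits = std.fit_transform(scaled)

    profiler = TrophicProfiler(
        fsp,
        optima=config.optima or None,
        ddof=config.ddof,
        zero_variance=config.zero_variance,
    ).fit(z_traits)
    tp = profiler.transform(z_traits)

    species = pd.Series({r.specimen_id: r.species for r in records})
    mean_tp = mean_trophic_profiles(tp, species)

    pca_traits = PCAOrdination().fit(z_traits)
    pca_tp = PCAOrdination().fit(tp)

    mean_tp_values = mean_tp.drop(columns="n")
    trees = {
        "species": WardClusterer(
            axis="rows", n_boot=config.n_boot, random_state=config.seed
        ).fit(mean_tp_values).dendrogram_,
        "food_types": WardClusterer(
            axis="columns", n_boot=config.n_boot, random_state=config.seed + 1
        ).fit(mean_tp_values).dendrogram_,
    }
    return scaled, z_traits, profiler, tp, mean_tp, pca_traits, pca_tp, trees


def run_pipeline(config: PipelineConfig, schema: TraitSchema = DEFAULT_SCHEMA) -> dict:
    """Execute the full analysis; write outputs to ``config.outdir``.

    Returns the run report (also written as ``report.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records = load_measurements(
        config.measurements, schema, aliases=config.aliases, sheet=config.sheet
    )
    complete = filter_complete(records, schema)
    if not complete:
        raise ValueError("no complete specimens after filtering")
    fsp = read_fsp(config.fsp, schema=schema, optimum_traits=set(config.optimum_traits))

    summary = summarize_species(complete, ddof=config.ddof)
    (scaled, z_traits, profiler, tp, mean_tp, pca_traits, pca_tp, trees) = _fit_stages(
        complete, fsp, schema, config
    )

    species = pd.Series({r.specimen_id: r.species for r in complete})
    write_species_summary(summary, outdir / "species_summary.csv")
    write_trophic_profiles(tp, species, outdir / "trophic_profiles.csv")
    mean_tp.to_csv(outdir / "mean_trophic_profiles.csv")
    pca_traits.scores_.to_csv(outdir / "pca_traits_scores.csv")
    pca_traits.loadings_.to_csv(outdir / "pca_traits_loadings.csv")
    pca_tp.scores_.to_csv(outdir / "pca_tp_scores.csv")
    pca_tp.loadings_.to_csv(outdir / "pca_tp_loadings.csv")
    for name, dendro in trees.items():
        (outdir / f"{name}_dendrogram.nwk").write_text(dendro.to_newick() + "\n")
        dendro.support_table().to_csv(outdir / f"{name}_clade_support.csv", index=False)

    k = min(config.pca_components, len(pca_traits.explained_fraction_))
    k_tp = min(config.pca_components, len(pca_tp.explained_fraction_))
    report = {
        "config": asdict(config),
        "version": __version__,
        "n_rows_loaded": len(records),
        "n_specimens": len(complete),
        "n_species": int(summary.shape[0]),
        "n_traits_retained": len(z_traits.columns),
        "n_food_types": len(fsp.food_types),
        "pca": {
            "traits_explained_fraction": [float(v) for v in pca_traits.explained_fraction_],
            "traits_first_k": float(pca_traits.explained_first_k(k)),
            "tp_explained_fraction": [float(v) for v in pca_tp.explained_fraction_],
            "tp_first_k": float(pca_tp.explained_first_k(k_tp)),
            "k": k,
        },
        "clustering": {
            name: {
                "n_boot": dendro.n_boot,
                "seed": dendro.seed,
                "support": {
                    ";".join(sorted(c)): s for c, s in sorted(
                        dendro.support.items(), key=lambda kv: sorted(kv[0])
                    )
                },
            }
            for name, dendro in trees.items()
        },
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    logger.info(
        "pipeline: %d specimens, %d species, %d food types -> %s",
        len(complete), summary.shape[0], len(fsp.food_types), outdir,
    )
    return report
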