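"""Config-driven orchestration: filter -> core -> neutral -> diversity ->
exposome, with a run manifest for provenance."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .contingency import ContingencyResult, attractor_summary
from .data_io import (
    drop_control_samples,
    filter_low_yield_samples,
    filter_taxa_by_lineage,
    read_abundance_table,
    read_metadata,
    read_taxonomy,
    remove_contaminants,
    write_abundance_table,
)
from .diversity import alpha_diversity, permanova_by_covariates
from .neutral import fit_migration
from .occupancy import select_core
from .table import AbundanceTable, SampleMetadata, TaxonomyTable

log = logging.getLogger("coreniche")


@dataclass
class PipelineConfig:
    table: str = ""
    table_format: str = "tsv"
    metadata: str = ""
    taxonomy: str = ""
    out_dir: str = "coreniche_out"
    min_reads: int = 2000
    exclude_lineages: list = field(
        default_factory=lambda: [["Family", "Mitochondria"], ["Order", "Chloroplast"]]
    )
    drop_unassigned: bool = True
    contaminant_threshold: float = 0.1
    occupancy_schemes: list = field(default_factory=lambda: ["none"])
    stopping_criterion: str = "last2pct"
    neutral_confidence: float = 0.95
    permanova_covariates: list = field(default_factory=list)
    n_permutations: int = 999
    exposome_anchor: str = ""
    exposome_pairs: list = field(default_factory=list)
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def validate_config(config: PipelineConfig, metadata: SampleMetadata) -> None:
    """Fail fast on covariates the config references but metadata lacks."""
    referenced = set(config.permanova_covariates)
    referenced.update(s for s in config.occupancy_schemes if s != "none")
    if config.exposome_anchor:
        referenced.add(config.exposome_anchor)
    for pair in config.exposome_pairs:
        referenced.update(pair)
    missing = referenced - set(metadata.covariates)
    if missing:
        raise ValueError(f"covariates missing from metadata: {sorted(missing)}")


def apply_filters(table: AbundanceTable, metadata: SampleMetadata,
                  taxonomy: TaxonomyTable | None, config: PipelineConfig
                  ) -> tuple[AbundanceTable, dict]:
    """Lineage exclusions, contaminant removal, control drop, depth filter."""
    stats: dict = {"n_taxa_in": table.n_taxa, "n_samples_in": table.n_samples}
    if taxonomy is not None:
        table, rep = filter_taxa_by_lineage(
            table, taxonomy,
            [(r, v) for r, v in config.exclude_lineages],
            drop_fully_unassigned=config.drop_unassigned,
        )
        stats["lineage_removed"] = len(rep.removed_taxa)
    if metadata.is_control().any():
        table, rep = remove_contaminants(table, metadata,
                                         config.contaminant_threshold)
        stats["contaminants_removed"] = len(rep.removed_taxa)
        table = drop_control_samples(table, metadata)
    table, rep = filter_low_yield_samples(table, config.min_reads)
    stats["low_yield_removed"] = len(rep.removed_samples)
    stats["n_taxa_out"] = table.n_taxa
    stats["n_samples_out"] = table.n_samples
    stats["median_depth"] = float(table.depths().median())
    return table, stats


def run_core_pipeline(config: PipelineConfig,
                      table: AbundanceTable | None = None,
                      metadata: SampleMetadata | None = None,
                      taxonomy: TaxonomyTable | None = None) -> dict:
    """Core/neutral stage per occupancy scheme; writes a TSV bundle.

    Returns {"filtered_table", "filter_stats", "schemes": {scheme:
    {"core": CoreSelection, "neutral": NeutralFit}}, "manifest"}.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if table is None:
        table = read_abundance_table(config.table, config.table_format)
    if metadata is None:
        metadata = read_metadata(config.metadata)
    if taxonomy is None and config.taxonomy:
        taxonomy = read_taxonomy(config.taxonomy)
    validate_config(config, metadata)

    table, filter_stats = apply_filters(table, metadata, taxonomy, config)
    log.info("filtered table: %d samples x %d taxa", *table.shape)
    write_abundance_table(table, out_dir / "filtered_table.tsv")

    schemes = {}
    for scheme in config.occupancy_schemes:
        log.info("occupancy scheme %r", scheme)
        core = select_core(table, metadata, grouping=scheme)
        fit = fit_migration(table, confidence=config.neutral_confidence)
        schemes[scheme] = {"core": core, "neutral": fit}
        frame = core.to_frame(taxonomy)
        frame["neutral_label"] = fit.taxa["label"].reindex(frame.index)
        frame.to_csv(out_dir / f"core_{scheme}.tsv", sep="\t")
        fit.taxa.to_csv(out_dir / f"neutral_{scheme}.tsv", sep="\t")
        with open(out_dir / f"neutral_{scheme}_summary.json", "w") as fh:
            json.dump(fit.summary(), fh, indent=2)

    if config.permanova_covariates:
        meta_sub = metadata.subset(table.sample_ids)
        alpha_diversity(table).to_csv(out_dir / "alpha_diversity.tsv", sep="\t")
        permanova_by_covariates(
            table, meta_sub, config.permanova_covariates,
            config.n_permutations, config.seed,
        ).to_csv(out_dir / "permanova.tsv", sep="\t", index=False)

    manifest = {
        "coreniche_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "filter_stats": filter_stats,
        "schemes": {
            s: {"k_last2pct": v["core"].k_last2pct,
                "k_elbow": v["core"].k_elbow,
                "min_core_occupancy": v["core"].min_core_occupancy(
                    config.stopping_criterion),
                "m": v["neutral"].m, "r_squared": v["neutral"].r_squared}
            for s, v in schemes.items()
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {"filtered_table": table, "filter_stats": filter_stats,
            "schemes": schemes, "manifest": manifest}


def run_exposome_pipeline(config: PipelineConfig,
                          metadata: SampleMetadata | None = None) -> dict:
    """Chi-square/residual tests of each configured pair; attractor summary."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if metadata is None:
        metadata = read_metadata(config.metadata)
    validate_config(config, metadata)
    df = metadata.data.loc[~metadata.is_control(), metadata.covariates]

    results = []
    rows = []
    for a, b in config.exposome_pairs:
        res = ContingencyResult.from_metadata(df, a, b)
        results.append(res)
        rows.append({"covariate_a": a, "covariate_b": b, "chi2": res.chi2,
                     "dof": res.dof, "p": res.p_value})
        long = res.residuals.stack().rename("residual").reset_index()
        long.columns = [a, b, "residual"]
        long.to_csv(out_dir / f"residuals_{a}_vs_{b}.tsv", sep="\t", index=False)
    tests = pd.DataFrame(rows, columns=["covariate_a", "covariate_b",
                                        "chi2", "dof", "p"])
    tests.to_csv(out_dir / "contingency_tests.tsv", sep="\t", index=False)

    summary = pd.DataFrame()
    if config.exposome_anchor:
        summary = attractor_summary(results, config.exposome_anchor, config.alpha)
        summary.to_csv(out_dir / "attractor_summary.tsv", sep="\t", index=False)
    return {"tests": tests, "results": results, "summary": summary}
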