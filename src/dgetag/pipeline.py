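"""End-to-end pipeline: QC -> mapping -> DE -> enrichment -> clustering.

``run_pipeline`` is a pure function of (inputs, config, seed): it reads
the design table and per-library FASTQ/TSV inputs, builds the reference
tag databases, cleans and maps every library, runs every within-species
stage contrast and every between-species stage contrast, computes DEG
overlap counts, term enrichment, and the between-species log-ratio
clustering, and writes everything as TSV (plus a Newick dendrogram) into
the output directory.  Every TSV carries the config hash in a leading
comment line; a manifest records it for the remaining formats.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from . import design as design_mod
from . import noiseq
from .clustering import hierarchical_cluster, log_ratio_matrix
from .design import Design, replicate_correlations
from .enrichment import AnnotationTable, enrich
from .tag_mapping import ExpressionMatrix, map_library, mapping_summary_frame
from .tag_qc import (
    abundance_profile,
    library_from_fastq,
    library_from_tsv,
    saturation_curve,
)
from .tag_reference import build_genome_db, build_transcript_db

logger = logging.getLogger("dgetag")

_CONFIG_KEYS = {
    "transcript_fasta",
    "genome_fasta",
    "design_table",
    "annotation_table",
    "output_dir",
    "adaptor",
    "quality_floor",
    "max_mismatch",
    "anchor_strict",
    "pseudo",
    "q_threshold",
    "m_threshold",
    "p_alpha",
    "q_alpha",
    "cluster_method",
    "cluster_metric",
    "saturation_depths",
    "workers_per_library",
    "seed",
}


@dataclass
class PipelineConfig:
    """Validated run configuration; unknown keys are rejected."""

    transcript_fasta: str
    design_table: str
    output_dir: str
    genome_fasta: Optional[str] = None
    annotation_table: Optional[str] = None
    adaptor: str = ""
    quality_floor: int = 10
    max_mismatch: int = 1
    anchor_strict: bool = True
    pseudo: float = noiseq.DEFAULT_PSEUDO
    q_threshold: float = noiseq.DEFAULT_Q_THRESHOLD
    m_threshold: float = noiseq.DEFAULT_M_THRESHOLD
    p_alpha: float = 0.05
    q_alpha: float = 0.05
    cluster_method: str = "average"
    cluster_metric: str = "euclidean"
    saturation_depths: list[int] = field(
        default_factory=lambda: [1000, 5000, 10000, 25000, 50000, 100000]
    )
    workers_per_library: int = design_mod.DEFAULT_WORKERS_PER_LIBRARY
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def sha256(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    design: Design
    libraries: dict
    expr: ExpressionMatrix
    mapping_summary: pd.DataFrame
    de_results: dict[str, noiseq.DEResult]
    overlaps: dict[str, pd.DataFrame]
    enrichments: dict[str, pd.DataFrame]
    ratio_matrix: object
    dendrogram: object
    replicate_corr: pd.DataFrame


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str, index=True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_sha256={config_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.sha256()
    logging.basicConfig(level=logging.INFO, format="%(name)s %(levelname)s %(message)s")

    stage = "design"
    try:
        design = Design.from_tsv(
            config.design_table, workers_per_library=config.workers_per_library
        )
        logger.info("design: %d libraries, %d pooled workers",
                    design.n_libraries, design.pooled_workers)

        stage = "reference"
        tdb = build_transcript_db(config.transcript_fasta)
        gdb = build_genome_db(config.genome_fasta) if config.genome_fasta else None
        logger.info("reference: %d distinct transcript tags", tdb.n_distinct_tags)

        stage = "qc"
        libraries = {}
        qc_rows, profiles, sat_frames = [], [], []
        for row in design.table.itertuples(index=False):
            path = Path(row.path)
            reader = library_from_fastq if path.suffix in {".fastq", ".fq"} else library_from_tsv
            lib = reader(
                path,
                adaptor=config.adaptor,
                quality_floor=config.quality_floor,
                library_id=row.library_id,
                species=row.species,
                stage=row.stage,
                replicate=int(row.replicate),
            )
            libraries[row.library_id] = lib
            qc_rows.append(lib.qc_row())
            prof = abundance_profile(lib).to_frame()
            prof.insert(0, "library_id", row.library_id)
            profiles.append(prof)
            sat = saturation_curve(
                lib, tdb,
                [d for d in config.saturation_depths if d <= lib.clean_tags] or [lib.clean_tags],
                seed=config.seed,
                max_mismatch=config.max_mismatch,
            )
            sat.insert(0, "library_id", row.library_id)
            sat_frames.append(sat)
            logger.info("qc %s: %d raw -> %d clean tags",
                        row.library_id, lib.raw_tags, lib.clean_tags)
        _write_tsv(pd.DataFrame(qc_rows).fillna(0), out / "qc_summary.tsv", chash, index=False)
        _write_tsv(pd.concat(profiles), out / "abundance_profiles.tsv", chash, index=False)
        _write_tsv(pd.concat(sat_frames), out / "saturation.tsv", chash, index=False)

        stage = "mapping"
        columns, summaries = [], []
        for lib_id, lib in libraries.items():
            col, summ = map_library(
                lib, tdb, gdb,
                max_mismatch=config.max_mismatch,
                anchor_strict=config.anchor_strict,
            )
            columns.append(col)
            summaries.append(summ)
        expr = ExpressionMatrix.from_columns(
            columns, {lib_id: lib.clean_tags for lib_id, lib in libraries.items()}
        )
        map_frame = mapping_summary_frame(summaries)
        _write_tsv(map_frame, out / "mapping_summary.tsv", chash, index=False)
        expr.to_tsv(out / "expression_matrix.tsv")
        rep_corr = replicate_correlations(expr.tpm, design)
        _write_tsv(rep_corr, out / "replicate_correlations.tsv", chash, index=False)

        stage = "de"
        contrasts = []
        for sp in design.species:
            contrasts.extend(design.stage_contrasts(sp))
        contrasts.extend(design.species_contrasts())
        de_results: dict[str, noiseq.DEResult] = {}
        summary_rows = []
        for contrast in contrasts:
            res = noiseq.run_contrast(
                expr.tpm, contrast,
                pseudo=config.pseudo,
                q_threshold=config.q_threshold,
                m_threshold=config.m_threshold,
            )
            de_results[contrast.label] = res
            summary_rows.append(res.summary())
            safe = contrast.label.replace(":", "__")
            _write_tsv(res.table, out / f"de_{safe}.tsv", chash)
            logger.info("de %s: %d significant", contrast.label, res.summary()["n_significant"])
        _write_tsv(pd.DataFrame(summary_rows), out / "de_summary.tsv", chash, index=False)

        stage = "overlaps"
        overlaps = {}
        for sp in design.species:
            sets = {
                c.label: de_results[c.label].significant_genes
                for c in design.stage_contrasts(sp)
            }
            overlaps[sp] = noiseq.overlap_counts(sets)
            _write_tsv(overlaps[sp], out / f"overlap_stages_{sp}.tsv", chash, index=False)
        sp_sets = {
            c.label: de_results[c.label].significant_genes
            for c in design.species_contrasts()
        }
        overlaps["between_species"] = noiseq.overlap_counts(sp_sets)
        _write_tsv(overlaps["between_species"], out / "overlap_species.tsv", chash, index=False)

        stage = "enrichment"
        enrichments = {}
        if config.annotation_table:
            annotation = AnnotationTable.from_tsv(config.annotation_table)
            for label, res in de_results.items():
                degs = res.significant_genes
                if not degs:
                    continue
                table = enrich(degs, annotation, config.p_alpha, config.q_alpha)
                enrichments[label] = table
                safe = label.replace(":", "__")
                _write_tsv(table, out / f"enrichment_{safe}.tsv", chash, index=False)

        stage = "clustering"
        ratio = None
        dendro = None
        union_species_degs = sorted(set().union(*(s for s in sp_sets.values())) or set())
        if len(union_species_degs) >= 2 and len(design.species) == 2:
            sp1, sp2 = design.species
            ratio = log_ratio_matrix(
                expr.tpm,
                {st: design.libraries(sp1, st) for st in design.stages},
                {st: design.libraries(sp2, st) for st in design.stages},
                gene_set=union_species_degs,
            )
            dendro = hierarchical_cluster(
                ratio, method=config.cluster_method, metric=config.cluster_metric
            )
            _write_tsv(ratio.values.round(6), out / "ratio_matrix.tsv", chash)
            _write_tsv(
                ratio.values.loc[dendro.leaf_order].round(6),
                out / "ratio_matrix_leaf_ordered.tsv",
                chash,
            )
            (out / "dendrogram.newick").write_text(dendro.to_newick() + "\n")

        manifest = {
            "config_sha256": chash,
            "config": asdict(config),
            "n_libraries": design.n_libraries,
            "pooled_workers": design.pooled_workers,
            "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return PipelineResult(
        config=config,
        design=design,
        libraries=libraries,
        expr=expr,
        mapping_summary=map_frame,
        de_results=de_results,
        overlaps=overlaps,
        enrichments=enrichments,
        ratio_matrix=ratio,
        dendrogram=dendro,
        replicate_corr=rep_corr,
    )
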