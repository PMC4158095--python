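"""Tag-to-gene mapping, mapping-category accounting, and TPM normalization.

Clean tags are looked up in the transcript tag database (exact first,
then one mismatch).  A tag whose matches all fall in a single gene is
*unambiguous* and contributes its full copy number to that gene's count;
tags hitting several genes count toward all-mapped mass only; tags with
no transcript hit fall through to the genome database, and whatever
remains is "unknown".  Counts are normalized to TPM — tags per million
clean tags — using the library's clean-tag total as denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .tag_qc import TagLibrary
from .tag_reference import ReferenceTagDB, lookup


@dataclass
class MappingSummary:
    """Per-library Table-1-style mapping category masses.

    Invariant: gene_mapped_mass + genome_mapped_mass + unknown_mass ==
    clean_tags (genome mass stays 0 when no genome db is supplied and the
    category is reported as not assessed).
    """

    library_id: str
    clean_tags: int
    gene_mapped_mass: int
    unambiguous_mass: int
    genes_with_any_tag: int
    genes_with_unambiguous_tag: int
    genome_mapped_mass: int
    unknown_mass: int
    genome_assessed: bool

    def to_row(self) -> dict:
        c = self.clean_tags or 1
        return {
            "library_id": self.library_id,
            "clean_tags": self.clean_tags,
            "all_tag_mapped_to_gene": self.gene_mapped_mass,
            "all_tag_mapped_to_gene_pct": 100.0 * self.gene_mapped_mass / c,
            "unambiguous_tag_mass": self.unambiguous_mass,
            "unambiguous_tag_pct": 100.0 * self.unambiguous_mass / c,
            "genes_with_any_tag": self.genes_with_any_tag,
            "genes_with_unambiguous_tag": self.genes_with_unambiguous_tag,
            "mapped_to_genome": self.genome_mapped_mass,
            "mapped_to_genome_pct": 100.0 * self.genome_mapped_mass / c,
            "unknown_tags": self.unknown_mass,
            "unknown_tag_pct": 100.0 * self.unknown_mass / c,
            "genome_assessed": self.genome_assessed,
        }


def map_library(
    lib: TagLibrary,
    tdb: ReferenceTagDB,
    gdb: Optional[ReferenceTagDB] = None,
    max_mismatch: int = 1,
    anchor_strict: bool = True,
) -> tuple[pd.Series, MappingSummary]:
    """Map one clean library; return per-gene unambiguous counts + summary."""
    if tdb.source_kind != "transcript":
        raise ValueError("tdb must be a transcript-kind database")
    counts: dict[str, int] = {}
    gene_mass = 0
    unambiguous_mass = 0
    genome_mass = 0
    unknown_mass = 0
    any_genes: set[str] = set()
    for tag, n in lib.tags.items():
        rep = lookup(tdb, tag, max_mismatch=max_mismatch, anchor_strict=anchor_strict)
        if rep.hit:
            gene_mass += n
            any_genes |= rep.sources
            if rep.unambiguous:
                (gene,) = rep.sources
                counts[gene] = counts.get(gene, 0) + n
                unambiguous_mass += n
        elif gdb is not None and lookup(
            gdb, tag, max_mismatch=max_mismatch, anchor_strict=anchor_strict
        ).hit:
            genome_mass += n
        else:
            unknown_mass += n
    summary = MappingSummary(
        library_id=lib.library_id,
        clean_tags=lib.clean_tags,
        gene_mapped_mass=gene_mass,
        unambiguous_mass=unambiguous_mass,
        genes_with_any_tag=len(any_genes),
        genes_with_unambiguous_tag=len(counts),
        genome_mapped_mass=genome_mass,
        unknown_mass=unknown_mass,
        genome_assessed=gdb is not None,
    )
    return pd.Series(counts, dtype="int64", name=lib.library_id), summary


def tpm_normalize(counts: pd.DataFrame, denominators: pd.Series) -> pd.DataFrame:
    """Scale each library column to tags per million clean tags.

    The denominator is the library's clean-tag total (the protocol's "per
    million clean tags"), not the unambiguously mapped mass, so TPM columns
    do not generally sum to 1e6.
    """
    denominators = denominators.reindex(counts.columns)
    if denominators.isna().any() or (denominators <= 0).any():
        bad = denominators[denominators.isna() | (denominators <= 0)].index.tolist()
        raise ValueError(f"invalid TPM denominators for libraries: {bad}")
    return counts / denominators * 1e6


@dataclass
class ExpressionMatrix:
    """Genes x libraries unambiguous counts and TPM, with denominators."""

    counts: pd.DataFrame
    denominators: pd.Series
    tpm: pd.DataFrame

    @classmethod
    def from_columns(
        cls, columns: Sequence[pd.Series], denominators: dict[str, int]
    ) -> "ExpressionMatrix":
        counts = pd.concat(columns, axis=1).fillna(0).astype("int64")
        counts = counts.sort_index()
        denom = pd.Series(denominators, dtype="float64").reindex(counts.columns)
        return cls(counts=counts, denominators=denom, tpm=tpm_normalize(counts, denom))

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path) -> None:
        out = pd.concat(
            {"count": self.counts, "tpm": self.tpm.round(4)}, axis=1
        ).swaplevel(axis=1).sort_index(axis=1)
        out.columns = [f"{lib}_{kind}" for lib, kind in out.columns]
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


def mapping_summary_frame(summaries: Sequence[MappingSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_row() for s in summaries])
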