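"""Experiment design table: species x stage x replicate -> library.

The reference design is two honeybee species x three hypopharyngeal-gland
developmental stages (newly emerged worker, nurse, forager) x two
biological replicates = 12 libraries, each built from the pooled glands
of 60 workers (720 workers in total).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import pandas as pd

from .noiseq import Contrast

STAGES = ("newly_emerged", "nurse", "forager")
DEFAULT_WORKERS_PER_LIBRARY = 60


@dataclass
class Design:
    """Validated experiment design with contrast construction helpers."""

    table: pd.DataFrame  # columns: library_id, species, stage, replicate, path
    workers_per_library: int = DEFAULT_WORKERS_PER_LIBRARY

    def __post_init__(self) -> None:
        required = {"library_id", "species", "stage", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        if self.table["library_id"].duplicated().any():
            raise ValueError("duplicate library ids in design table")
        dup = self.table.duplicated(subset=["species", "stage", "replicate"])
        if dup.any():
            raise ValueError("duplicate (species, stage, replicate) cells in design")

    @classmethod
    def from_tsv(cls, path: Union[str, Path], **kwargs) -> "Design":
        table = pd.read_csv(path, sep="\t", comment="#")
        if "path" in table.columns:
            base = Path(path).parent
            table["path"] = [
                str(p) if Path(p).is_absolute() else str(base / p)
                for p in table["path"]
            ]
        return cls(table, **kwargs)

    @property
    def species(self) -> list[str]:
        return sorted(self.table["species"].unique())

    @property
    def stages(self) -> list[str]:
        order = [s for s in STAGES if s in set(self.table["stage"])]
        extra = sorted(set(self.table["stage"]) - set(order))
        return order + extra

    @property
    def n_libraries(self) -> int:
        return len(self.table)

    @property
    def pooled_workers(self) -> int:
        """Total animals pooled across all libraries (12 x 60 = 720)."""
        return self.n_libraries * self.workers_per_library

    def libraries(self, species: str, stage: str) -> list[str]:
        sel = self.table[
            (self.table["species"] == species) & (self.table["stage"] == stage)
        ].sort_values("replicate")
        return sel["library_id"].tolist()

    def stage_contrasts(self, species: str) -> list[Contrast]:
        """All pairwise within-species stage contrasts (stage1 vs stage2)."""
        stages = self.stages
        out = []
        for i in range(len(stages)):
            for j in range(i + 1, len(stages)):
                out.append(
                    Contrast(
                        label=f"{species}:{stages[i]}_vs_{stages[j]}",
                        condition_1=self.libraries(species, stages[i]),
                        condition_2=self.libraries(species, stages[j]),
                    )
                )
        return out

    def species_contrasts(self) -> list[Contrast]:
        """Between-species contrast at each stage (species1 vs species2)."""
        if len(self.species) != 2:
            raise ValueError("species contrasts need exactly 2 species")
        sp1, sp2 = self.species
        return [
            Contrast(
                label=f"{sp1}_vs_{sp2}:{stage}",
                condition_1=self.libraries(sp1, stage),
                condition_2=self.libraries(sp2, stage),
            )
            for stage in self.stages
        ]

    def validate_full_factorial(
        self, n_species: int = 2, n_stages: int = 3, n_replicates: int = 2
    ) -> dict:
        """Check the full-factorial layout and report the design arithmetic."""
        if len(self.species) != n_species:
            raise ValueError(f"expected {n_species} species, found {len(self.species)}")
        if len(self.stages) != n_stages:
            raise ValueError(f"expected {n_stages} stages, found {len(self.stages)}")
        for sp in self.species:
            for st in self.stages:
                libs = self.libraries(sp, st)
                if len(libs) != n_replicates:
                    raise ValueError(
                        f"cell ({sp}, {st}) has {len(libs)} replicates, expected {n_replicates}"
                    )
        return {
            "n_species": n_species,
            "n_stages": n_stages,
            "n_replicates": n_replicates,
            "n_libraries": self.n_libraries,
            "workers_per_library": self.workers_per_library,
            "pooled_workers": self.pooled_workers,
        }


def replicate_correlations(tpm: pd.DataFrame, design: Design) -> pd.DataFrame:
    """Pearson correlation of replicate TPM columns per (species, stage)."""
    rows = []
    for sp in design.species:
        for st in design.stages:
            libs = design.libraries(sp, st)
            if len(libs) < 2:
                continue
            r = float(tpm[libs[0]].corr(tpm[libs[1]]))
            rows.append({"species": sp, "stage": st, "pearson_r": r})
    return pd.DataFrame(rows)
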