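"""Raw-tag filtering, library QC accounting, and sequencing-saturation curves.

Raw DGE reads are 49 bp: the 21 bp tag (CATG anchor + 17 nt) followed by
adaptor sequence.  Cleaning removes, in order: empty / adaptor-only
records, reads not starting with the CATG anchor, tags containing N or a
base below the quality floor, tags of the wrong length (pre-counted TSV
input can carry those), and finally tags observed only once in the
library.  What survives is the library's "clean tag" multiset; all
removals are accounted per reason so raw = clean + removed holds exactly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union
import warnings

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .tag_reference import ANCHOR, TAG_LENGTH, ReferenceTagDB, lookup

DEFAULT_QUALITY_FLOOR = 10
#: copy-number bins of the abundance profile: [2,5], [6,10], ... , >100
ABUNDANCE_BINS: tuple[tuple[int, float], ...] = (
    (2, 5),
    (6, 10),
    (11, 20),
    (21, 50),
    (51, 100),
    (101, float("inf")),
)


@dataclass
class TagLibrary:
    """One sequencing library: clean-tag copy numbers plus QC accounting."""

    library_id: str
    species: str = ""
    stage: str = ""
    replicate: int = 0
    tags: dict[str, int] = field(default_factory=dict)
    raw_tags: int = 0
    filter_counts: dict[str, int] = field(default_factory=dict)

    @property
    def clean_tags(self) -> int:
        return sum(self.tags.values())

    @property
    def distinct_clean(self) -> int:
        return len(self.tags)

    def validate(self) -> None:
        for tag, n in self.tags.items():
            if len(tag) != TAG_LENGTH:
                raise ValueError(f"retained tag of length {len(tag)}: {tag}")
            if n < 2:
                raise ValueError(f"retained singleton tag: {tag}")
        if self.raw_tags != self.clean_tags + sum(self.filter_counts.values()):
            raise ValueError("tag-mass accounting violated")

    def qc_row(self) -> dict:
        """One Table-1-style accounting row for this library."""
        raw = self.raw_tags
        clean = self.clean_tags
        distinct_raw = self.filter_counts.get("singleton", 0) + self.distinct_clean
        return {
            "library_id": self.library_id,
            "raw_tags": raw,
            "distinct_raw_lower_bound": distinct_raw,
            "clean_tags": clean,
            "clean_pct": 100.0 * clean / raw if raw else 0.0,
            "distinct_clean": self.distinct_clean,
            **{f"removed_{k}": v for k, v in sorted(self.filter_counts.items())},
        }


def clean_library(
    raw: Iterable[Union[str, tuple[str, Optional[str]]]],
    adaptor: str = "",
    quality_floor: int = DEFAULT_QUALITY_FLOOR,
    library_id: str = "",
    species: str = "",
    stage: str = "",
    replicate: int = 0,
) -> TagLibrary:
    """Filter raw records into a clean TagLibrary.

    ``raw`` yields read strings or ``(read, quality)`` pairs (quality is a
    Phred+33 string or None).  Reads longer than the tag are truncated to
    the first 21 bases after anchor detection at position 0; reads not
    starting with CATG count under ``anchor_missing``.
    """
    counts: Counter[str] = Counter()
    removed: Counter[str] = Counter()
    n_raw = 0
    for rec in raw:
        seq, qual = rec if isinstance(rec, tuple) else (rec, None)
        n_raw += 1
        if not seq:
            removed["empty"] += 1
            continue
        if adaptor and seq.startswith(adaptor):
            removed["adaptor_only"] += 1
            continue
        if len(seq) < TAG_LENGTH:
            removed["length"] += 1
            continue
        if not seq.startswith(ANCHOR):
            removed["anchor_missing"] += 1
            continue
        tag = seq[:TAG_LENGTH]
        if "N" in tag:
            removed["contains_n"] += 1
            continue
        if qual is not None and any(ord(q) - 33 < quality_floor for q in qual[:TAG_LENGTH]):
            removed["low_quality"] += 1
            continue
        counts[tag] += 1
    singles = [t for t, n in counts.items() if n < 2]
    for t in singles:
        removed["singleton"] += counts.pop(t)
    lib = TagLibrary(
        library_id=library_id,
        species=species,
        stage=stage,
        replicate=replicate,
        tags=dict(counts),
        raw_tags=n_raw,
        filter_counts=dict(removed),
    )
    lib.validate()
    return lib


def library_from_fastq(path: Union[str, Path], adaptor: str = "", **kwargs) -> TagLibrary:
    def records():
        with open(path) as fh:
            for _title, seq, qual in FastqGeneralIterator(fh):
                yield seq.upper(), qual

    return clean_library(records(), adaptor=adaptor, **kwargs)


def library_from_tsv(path: Union[str, Path], **kwargs) -> TagLibrary:
    """Read a pre-counted 2-column (tag, count) TSV and apply the filters."""
    df = pd.read_csv(path, sep="\t", header=None, names=["tag", "count"], comment="#")

    def records():
        for tag, n in zip(df["tag"], df["count"]):
            for _ in range(int(n)):
                yield str(tag).upper(), None

    return clean_library(records(), **kwargs)


@dataclass
class AbundanceProfile:
    """Copy-number-binned tag mass and distinct-tag counts (Figure-S3 style)."""

    bins: tuple[tuple[int, float], ...]
    mass: list[int]
    distinct: list[int]
    mass_fraction: list[float]
    distinct_fraction: list[float]

    def to_frame(self) -> pd.DataFrame:
        labels = [
            f"[{lo},{int(hi)}]" if hi != float("inf") else f">{lo - 1}"
            for lo, hi in self.bins
        ]
        return pd.DataFrame(
            {
                "bin": labels,
                "tag_mass": self.mass,
                "distinct_tags": self.distinct,
                "mass_fraction": self.mass_fraction,
                "distinct_fraction": self.distinct_fraction,
            }
        )


def abundance_profile(lib: TagLibrary, bins=ABUNDANCE_BINS) -> AbundanceProfile:
    mass = [0] * len(bins)
    distinct = [0] * len(bins)
    for n in lib.tags.values():
        for i, (lo, hi) in enumerate(bins):
            if lo <= n <= hi:
                mass[i] += n
                distinct[i] += 1
                break
    total_mass = lib.clean_tags
    total_distinct = lib.distinct_clean
    return AbundanceProfile(
        bins=tuple(bins),
        mass=mass,
        distinct=distinct,
        mass_fraction=[m / total_mass if total_mass else 0.0 for m in mass],
        distinct_fraction=[d / total_distinct if total_distinct else 0.0 for d in distinct],
    )


def saturation_curve(
    lib: TagLibrary,
    db: ReferenceTagDB,
    depths: Sequence[int],
    seed: int,
    max_mismatch: int = 1,
) -> pd.DataFrame:
    """Genes detected (>=1 unambiguous tag) at nested subsampling depths.

    One seeded permutation of the library's tag copies is drawn and every
    depth is a prefix of it, so larger samples contain smaller ones and the
    curve is monotone non-decreasing by construction, not just in
    expectation.  Depths beyond the library size are capped with a warning.
    """
    depths = list(depths)
    if any(b > a for a, b in zip(depths[1:], depths)):
        raise ValueError("depths must be ascending")
    distinct = list(lib.tags)
    gene_of: dict[str, Optional[str]] = {}
    for tag in distinct:
        rep = lookup(db, tag, max_mismatch=max_mismatch)
        gene_of[tag] = next(iter(rep.sources)) if rep.unambiguous else None
    expanded = np.repeat(
        np.arange(len(distinct)), [lib.tags[t] for t in distinct]
    )
    rng = np.random.default_rng(seed)
    rng.shuffle(expanded)
    rows = []
    seen: set[str] = set()
    pos = 0
    for depth in depths:
        capped = min(depth, len(expanded))
        if depth > len(expanded):
            warnings.warn(
                f"depth {depth} exceeds clean tags ({len(expanded)}); capped",
                stacklevel=2,
            )
        for idx in expanded[pos:capped]:
            g = gene_of[distinct[idx]]
            if g is not None:
                seen.add(g)
        pos = capped
        rows.append({"depth": capped, "genes_detected": len(seen)})
    return pd.DataFrame(rows)
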