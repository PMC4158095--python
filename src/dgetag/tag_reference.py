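"""Reference tag databases for restriction-anchored expression tags.

A DGE-tag library sequences one short tag per transcript molecule: the
NlaIII site (CATG) anchors the tag and MmeI releases the 17 bases
immediately downstream, so every informative tag is a 21-mer of the form
``CATG + 17 nt``.  To interpret a sequenced tag we pre-enumerate every
possible such 21-mer from the reference — transcripts on the sense strand
(tags derive from mRNA), the genome on both strands — and answer exact or
one-mismatch lookups against that index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO
from Bio.Seq import Seq

ANCHOR = "CATG"
TAG_DOWNSTREAM = 17
TAG_LENGTH = len(ANCHOR) + TAG_DOWNSTREAM  # 21
_VALID_BASES = frozenset("ACGT")


def extract_tags(sequence: str, min_downstream: int = TAG_DOWNSTREAM) -> list[tuple[int, str]]:
    """Enumerate all CATG-anchored tags in ``sequence``.

    Models in-silico NlaIII digestion followed by the MmeI cut
    ``min_downstream`` bases past the anchor.  Every CATG occurrence with a
    full downstream window of A/C/G/T yields one tag; windows containing
    any other character (N, IUPAC ambiguity) are skipped rather than
    raising.  Offsets are 0-based positions of the C of CATG, ascending.
    """
    seq = sequence.upper()
    tags: list[tuple[int, str]] = []
    pos = seq.find(ANCHOR)
    while pos != -1:
        window = seq[pos + 4 : pos + 4 + min_downstream]
        if len(window) == min_downstream and not (set(window) - _VALID_BASES):
            tags.append((pos, seq[pos : pos + 4 + min_downstream]))
        pos = seq.find(ANCHOR, pos + 1)
    return tags


@dataclass
class ReferenceTagDB:
    """Map from 21-mer tag sequence to the set of reference sources.

    For a transcript database sources are gene ids; for a genome database
    they are ``(seq_id, offset, strand)`` tuples with 0-based offsets on
    the forward strand and half-open intervals.
    """

    source_kind: str  # "transcript" | "genome"
    entries: dict[str, set] = field(default_factory=dict)

    @property
    def n_distinct_tags(self) -> int:
        return len(self.entries)

    def add(self, tag: str, source) -> None:
        self.entries.setdefault(tag, set()).add(source)

    def to_tsv(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write("tag\tsource_kind\tsource_ids\n")
            for tag in sorted(self.entries):
                ids = ",".join(sorted(str(s) for s in self.entries[tag]))
                fh.write(f"{tag}\t{self.source_kind}\t{ids}\n")


@dataclass
class MatchReport:
    """Result of a tag lookup: the matching sources and how they matched."""

    query: str
    sources: set
    n_mismatch: int | None  # 0 exact, 1 one-mismatch, None no hit
    unambiguous: bool

    @property
    def hit(self) -> bool:
        return self.n_mismatch is not None


def build_transcript_db(fasta_path: Union[str, Path]) -> ReferenceTagDB:
    """Enumerate sense-strand tags of every transcript in a FASTA file.

    A tag shared by several genes maps to all of them.  Duplicate record
    ids are a validation error.
    """
    db = ReferenceTagDB(source_kind="transcript")
    seen: set[str] = set()
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate FASTA record id: {record.id}")
        seen.add(record.id)
        for _, tag in extract_tags(str(record.seq)):
            db.add(tag, record.id)
    return db


def build_genome_db(fasta_path: Union[str, Path]) -> ReferenceTagDB:
    """Enumerate tags of every genome record on both strands.

    Sources are ``(seq_id, forward-strand offset, strand)``; a minus-strand
    tag at reverse-complement offset o on a record of length L occupies
    forward interval [L - o - 21, L - o).
    """
    db = ReferenceTagDB(source_kind="genome")
    seen: set[str] = set()
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate FASTA record id: {record.id}")
        seen.add(record.id)
        seq = str(record.seq).upper()
        for off, tag in extract_tags(seq):
            db.add(tag, (record.id, off, "+"))
        rc = str(Seq(seq).reverse_complement())
        n = len(seq)
        for off, tag in extract_tags(rc):
            db.add(tag, (record.id, n - off - TAG_LENGTH, "-"))
    return db


def _one_mismatch_variants(tag: str, anchor_strict: bool) -> Iterable[str]:
    start = len(ANCHOR) if anchor_strict else 0
    for i in range(start, len(tag)):
        orig = tag[i]
        for base in "ACGT":
            if base != orig:
                yield tag[:i] + base + tag[i + 1 :]


def lookup(
    db: ReferenceTagDB,
    tag: str,
    max_mismatch: int = 1,
    anchor_strict: bool = True,
) -> MatchReport:
    """Look up a tag, exact first, then (optionally) at Hamming distance 1.

    Exact hits take priority and are never mixed with one-mismatch hits.
    With ``anchor_strict`` (default) mismatches are tolerated only in the
    17 nt suffix — the CATG anchor is enzymatically defined so a mismatch
    there implies a different digestion product, not a sequencing error.
    """
    if len(tag) != TAG_LENGTH:
        raise ValueError(f"tag must be {TAG_LENGTH} nt, got {len(tag)}")
    exact = db.entries.get(tag)
    if exact:
        return MatchReport(tag, set(exact), 0, len(exact) == 1)
    if max_mismatch >= 1:
        sources: set = set()
        for variant in _one_mismatch_variants(tag, anchor_strict):
            hit = db.entries.get(variant)
            if hit:
                sources |= hit
        if sources:
            return MatchReport(tag, sources, 1, len(sources) == 1)
    return MatchReport(tag, set(), None, False)
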