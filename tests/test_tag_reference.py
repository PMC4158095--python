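"""Tag extraction and reference-database lookup against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dgetag.tag_reference import (
    TAG_LENGTH,
    build_genome_db,
    build_transcript_db,
    extract_tags,
    lookup,
)

DNA = st.text(alphabet="ACGTN", min_size=0, max_size=120)


def naive_extract(seq: str, k: int = 17):
    """Independent all-positions scan for CATG sites with clean windows."""
    seq = seq.upper()
    out = []
    for i in range(len(seq)):
        if seq[i : i + 4] == "CATG":
            window = seq[i + 4 : i + 4 + k]
            if len(window) == k and all(c in "ACGT" for c in window):
                out.append((i, seq[i : i + 4 + k]))
    return out


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def naive_lookup(entries, tag, max_mismatch, anchor_strict=True):
    """Full Hamming scan over every stored tag."""
    exact = {s for t, ss in entries.items() if t == tag for s in ss}
    if exact or max_mismatch == 0:
        return exact
    hits = set()
    for stored, sources in entries.items():
        if hamming(stored, tag) == 1:
            (pos,) = [i for i in range(TAG_LENGTH) if stored[i] != tag[i]]
            if not anchor_strict or pos >= 4:
                hits |= sources
    return hits


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestExtractTags:
    def test_single_site(self):
        assert extract_tags("CATG" + "A" * 17) == [(0, "CATG" + "A" * 17)]

    def test_no_sites(self):
        assert extract_tags("AAACCCGGGTTT" * 5) == []

    def test_empty_sequence(self):
        assert extract_tags("") == []

    def test_three_sites_one_truncated_matches_naive_scan(self):
        # 60 nt, three CATG sites, the last with only 10 nt downstream
        seq = "AA" + "CATG" + "A" * 17 + "CATG" + "C" * 17 + "CC" + "CATG" + "G" * 10
        assert len(seq) == 60
        tags = extract_tags(seq)
        assert len(tags) == 2
        assert tags == naive_extract(seq)

    def test_dirty_window_skipped_not_error(self):
        seq = "CATG" + "N" + "A" * 16
        assert extract_tags(seq) == []

    @settings(derandomize=True, max_examples=200)
    @given(DNA)
    def test_matches_naive_scan(self, seq):
        assert extract_tags(seq) == naive_extract(seq)

    def test_tags_are_21bp_catg_anchored(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        tags = extract_tags(seq)
        assert tags
        for off, tag in tags:
            assert len(tag) == 21
            assert tag.startswith("CATG")
            assert tag == seq[off : off + 21]


class TestTranscriptDB:
    def test_shared_tag_maps_to_both_genes(self, tmp_path):
        tag = "CATG" + "ACGTA" * 3 + "GG"
        fasta = tmp_path / "two.fasta"
        fasta.write_text(f">a\nTT{tag}TT\n>b\nGG{tag}\n")
        db = build_transcript_db(fasta)
        assert db.entries[tag] == {"a", "b"}

    def test_three_toy_genes_six_distinct_tags(self, toy_fasta):
        db = build_transcript_db(toy_fasta)
        assert db.n_distinct_tags == 6
        for tag, sources in db.entries.items():
            assert len(tag) == 21 and tag.startswith("CATG")
            assert sources

    def test_empty_fasta(self, tmp_path):
        fasta = tmp_path / "empty.fasta"
        fasta.write_text("")
        assert build_transcript_db(fasta).n_distinct_tags == 0

    def test_duplicate_record_id_rejected(self, tmp_path):
        fasta = tmp_path / "dup.fasta"
        fasta.write_text(">a\nCATGAAAAAAAAAAAAAAAAA\n>a\nCATGCCCCCCCCCCCCCCCCC\n")
        with pytest.raises(ValueError, match="duplicate"):
            build_transcript_db(fasta)


class TestGenomeDB:
    def test_reverse_strand_site_found(self, tmp_path):
        # CATG is its own reverse complement, so the forward strand always
        # shows the anchor too — but here it sits at the 3' end with no
        # downstream window, so only the minus strand yields a tag.
        tag = "CATG" + "A" * 17
        seq = revcomp(tag)  # = TTT...T + CATG
        assert extract_tags(seq) == []
        fasta = tmp_path / "g.fasta"
        fasta.write_text(f">chr\n{seq}\n")
        db = build_genome_db(fasta)
        assert set(db.entries) == {tag}
        strands = {s[2] for sources in db.entries.values() for s in sources}
        assert strands == {"-"}

    def test_both_strand_occurrence_one_key_two_sources(self, tmp_path):
        tag = "CATG" + "ACGTACGTACGTACGTA"
        seq = tag + "AAA" + revcomp(tag)
        fasta = tmp_path / "p.fasta"
        fasta.write_text(f">chr\n{seq}\n")
        db = build_genome_db(fasta)
        assert len(db.entries[tag]) == 2
        assert {s[2] for s in db.entries[tag]} == {"+", "-"}

    def test_forward_tag_recorded_with_plus_strand(self, tmp_path):
        tag = "CATG" + "A" * 17
        fasta = tmp_path / "f.fasta"
        fasta.write_text(f">chr\n{tag}\n")
        db = build_genome_db(fasta)
        assert ("chr", 0, "+") in db.entries[tag]

    def test_strand_symmetry_key_sets(self, tmp_path):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=800))
        (tmp_path / "fwd.fasta").write_text(f">s\n{seq}\n")
        (tmp_path / "rev.fasta").write_text(f">s\n{revcomp(seq)}\n")
        fwd = build_genome_db(tmp_path / "fwd.fasta")
        rev = build_genome_db(tmp_path / "rev.fasta")
        assert set(fwd.entries) == set(rev.entries)


class TestLookup:
    @pytest.fixture()
    def db(self, toy_fasta):
        return build_transcript_db(toy_fasta)

    def test_exact_hit(self, db):
        tag = next(iter(db.entries))
        rep = lookup(db, tag)
        assert rep.n_mismatch == 0
        assert rep.sources == db.entries[tag]

    def test_one_mismatch_suffix_hit(self, db):
        tag = next(iter(db.entries))
        query = tag[:9] + ("A" if tag[9] != "A" else "C") + tag[10:]
        if query in db.entries:
            pytest.skip("mutation collided with another stored tag")
        rep = lookup(db, query)
        assert rep.n_mismatch == 1
        assert db.entries[tag] <= rep.sources

    def test_anchor_mismatch_not_tolerated_by_default(self, db):
        tag = next(iter(db.entries))
        query = "G" + tag[1:]
        assert not lookup(db, query, anchor_strict=True).hit
        assert lookup(db, query, anchor_strict=False).n_mismatch == 1

    def test_wrong_length_rejected(self, db):
        with pytest.raises(ValueError, match="21"):
            lookup(db, "CATGAAA")

    def test_exact_results_subset_of_one_mismatch(self, db):
        for tag in db.entries:
            r0 = lookup(db, tag, max_mismatch=0)
            r1 = lookup(db, tag, max_mismatch=1)
            assert r0.sources <= r1.sources

    def test_randomized_db_matches_hamming_scan(self):
        from dgetag.tag_reference import ReferenceTagDB

        rng = np.random.default_rng(42)
        db = ReferenceTagDB(source_kind="transcript")
        stored = []
        for i in range(50):
            tag = "CATG" + "".join(rng.choice(list("ACGT"), size=17))
            db.add(tag, f"g{i % 20}")
            stored.append(tag)
        for q in range(200):
            if q % 2 == 0:
                base = stored[rng.integers(50)]
                pos = int(rng.integers(21))
                query = base[:pos] + rng.choice(list("ACGT")) + base[pos + 1 :]
            else:
                query = "CATG" + "".join(rng.choice(list("ACGT"), size=17))
            for mm in (0, 1):
                got = lookup(db, query, max_mismatch=mm).sources
                expected = naive_lookup(db.entries, query, mm)
                assert got == expected
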