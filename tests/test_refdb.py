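"""Reference database construction: scanner, locus catalog, junction refs, IO."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msirna._util import revcomp
from msirna.refdb import (
    ReferenceDB,
    TranscriptModel,
    build_junction_refs,
    build_locus_db,
    build_reference_db,
    read_reference,
    scan_homopolymers,
    write_reference,
)


def naive_runs(seq: str, min_len: int) -> list[tuple[int, str, int]]:
    """O(n^2) enumeration of maximal single-base runs (independent oracle)."""
    seq = seq.upper()
    out = []
    for i in range(len(seq)):
        if seq[i] == "N":
            continue
        if i > 0 and seq[i - 1] == seq[i]:
            continue
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            out.append((i, seq[i], j - i))
    return out


class TestScanHomopolymers:
    @pytest.mark.parametrize(
        "seq, min_len, expected",
        [
            ("ACGT", 5, []),
            ("GGAAAAACC", 5, [(2, "A", 5)]),
            ("TTTTTT", 5, [(0, "T", 6)]),
            ("AAAANAAAA", 4, [(0, "A", 4), (5, "A", 4)]),  # N interrupts
            ("NNNNNN", 5, []),
            ("", 5, []),
        ],
    )
    def test_examples(self, seq, min_len, expected):
        assert scan_homopolymers(seq, min_len) == expected

    @given(st.text(alphabet="ACGTN", max_size=200), st.integers(1, 6))
    @settings(max_examples=200, deadline=None)
    def test_matches_naive_oracle(self, seq, min_len):
        assert scan_homopolymers(seq, min_len) == naive_runs(seq, min_len)

    def test_min_len_validation(self):
        with pytest.raises(ValueError):
            scan_homopolymers("ACGT", 0)


class TestBuildLocusDb:
    def test_toy_utr3_locus(self, toy_genome, toy_transcripts):
        loci = build_locus_db(toy_transcripts[:1], toy_genome)
        assert len(loci) == 1
        m = loci[0]
        assert (m.region, m.repeat_base, m.ref_length) == ("utr3", "A", 7)
        assert (m.start, m.end) == (250, 257)
        assert m.locus_id == "G1|chrT|251|A|7|utr3"
        assert len(m.context_seq) == 60 and m.transcript_offset == 26
        assert m.context_seq == toy_genome["chrT"][224:284]

    def test_isoforms_merge_into_one_locus(self, toy_genome, toy_transcripts):
        loci = build_locus_db(toy_transcripts[:2], toy_genome)
        assert len(loci) == 1
        assert sorted(loci[0].transcript_ids) == ["T1", "T2"]

    def test_minus_strand_reports_transcript_orientation(self):
        rng = np.random.default_rng(5)
        import tests.conftest as cf

        seq = cf._background(rng, 300)
        cf._plant(seq, 120, "T", 9)  # genomic T9 -> transcript-orientation A9
        genome = {"c": "".join(seq)}
        t = TranscriptModel("tx", "g", "c", "-", [(50, 250)], (150, 250))
        loci = build_locus_db([t], genome)
        run_loci = [m for m in loci if m.start == 120]
        assert len(run_loci) == 1
        assert run_loci[0].repeat_base == "A"
        # L=9 -> 51 flank bases, 25 upstream (transcript orientation) / 26 down
        assert run_loci[0].context_seq == revcomp(genome["c"][120 - 26 : 129 + 25])
        assert run_loci[0].transcript_offset == 25

    def test_strand_involution(self, toy_genome, toy_transcripts):
        """Reverse-complementing genome + annotation preserves context sequences."""
        n = len(toy_genome["chrT"])
        flipped_genome = {"chrT": revcomp(toy_genome["chrT"])}
        flipped = []
        for t in toy_transcripts:
            flipped.append(
                TranscriptModel(
                    t.transcript_id,
                    t.gene_id,
                    "chrT",
                    "-" if t.strand == "+" else "+",
                    [(n - b, n - a) for a, b in t.exons],
                    (n - t.cds[1], n - t.cds[0]),
                )
            )
        fwd = {m.context_seq for m in build_locus_db(toy_transcripts, toy_genome)}
        rev = {m.context_seq for m in build_locus_db(flipped, flipped_genome)}
        assert fwd == rev

    def test_noncoding_transcript_skipped(self, toy_genome):
        t = TranscriptModel("nc", "G1", "chrT", "+", [(100, 340)], None)
        assert build_locus_db([t], toy_genome) == []

    def test_out_of_contig_errors(self, toy_genome):
        t = TranscriptModel("bad", "G1", "chrT", "+", [(100, 5000)], (100, 400))
        with pytest.raises(ValueError, match="bad"):
            build_locus_db([t], toy_genome)


class TestJunctionRefs:
    def test_toy_acceptor_pair(self, toy_genome, toy_transcripts):
        t3 = toy_transcripts[2]
        loci = build_locus_db([t3], toy_genome)
        juncs = build_junction_refs(t3, loci, toy_genome)
        assert len(juncs) == 2
        by_kind = {j.kind: j for j in juncs}
        exp, skip = by_kind["expected"], by_kind["skip"]
        for j in (exp, skip):
            assert j.site == "acceptor"
            assert j.site_distance_bp == 2
            assert j.skipped_exon_index == 1
            assert j.left_seq == toy_genome["chrT"][530:560]
        assert exp.right_seq == toy_genome["chrT"][600:630]
        assert skip.right_seq == toy_genome["chrT"][700:730]
        assert exp.pair_id == skip.pair_id

    def test_outside_window_no_junctions(self, toy_genome, toy_transcripts):
        t3 = toy_transcripts[2]
        loci = build_locus_db([t3], toy_genome)
        assert build_junction_refs(t3, loci, toy_genome, window=1) == []

    def test_two_exon_transcript_expected_only(self, toy_genome):
        # middle exon removed: the T17 run now sits 2 nt before the acceptor
        # of the LAST exon, so a skip junction is structurally impossible
        t = TranscriptModel("T2x", "G2", "chrT", "+", [(500, 560), (600, 640)], (500, 640))
        loci = build_locus_db([t], toy_genome)
        juncs = build_junction_refs(t, loci, toy_genome)
        assert [j.kind for j in juncs] == ["expected"]

    def test_pairing_invariant(self, small_cohort):
        pairs = small_cohort.ref.db.junction_pairs()
        for members in pairs.values():
            kinds = sorted(j.kind for j in members)
            assert kinds in (["expected"], ["expected", "skip"])
            if len(members) == 2:
                assert members[0].skipped_exon_index == members[1].skipped_exon_index


class TestReferenceIO:
    def test_round_trip(self, toy_genome, toy_transcripts, tmp_path):
        db = build_reference_db(toy_transcripts, toy_genome)
        assert len(db.loci) == 2 and len(db.junctions) == 2
        fa, cat = tmp_path / "ref.fa", tmp_path / "ref.tsv"
        write_reference(db, fa, cat)
        back = read_reference(fa, cat)
        assert set(back.loci) == set(db.loci)
        for lid, m in db.loci.items():
            b = back.loci[lid]
            assert (b.context_seq, b.transcript_offset, b.ref_length, b.start, b.end) == (
                m.context_seq,
                m.transcript_offset,
                m.ref_length,
                m.start,
                m.end,
            )
            assert sorted(b.transcript_ids) == sorted(m.transcript_ids)
        for jid, j in db.junctions.items():
            b = back.junctions[jid]
            assert (b.left_seq, b.right_seq, b.kind, b.pair_id, b.site_distance_bp) == (
                j.left_seq,
                j.right_seq,
                j.kind,
                j.pair_id,
                j.site_distance_bp,
            )

    def test_fasta_record_count(self, toy_genome, toy_transcripts, tmp_path):
        from Bio import SeqIO

        db = build_reference_db(toy_transcripts, toy_genome)
        write_reference(db, tmp_path / "r.fa", tmp_path / "r.tsv")
        n = sum(1 for _ in SeqIO.parse(str(tmp_path / "r.fa"), "fasta"))
        assert n == len(db.loci) + len(db.junctions) == 4

    def test_truncated_context_flagged_and_written(self, tmp_path):
        # run one base from the contig start: context cannot reach 60 nt
        genome = {"c": "C" + "A" * 7 + "GTCGTACGATCGTACGTAGCTAGCTAGG" * 3}
        t = TranscriptModel("t", "g", "c", "+", [(0, 80)], (0, 80))
        loci = build_locus_db([t], genome)
        assert len(loci) == 1 and loci[0].truncated
        assert len(loci[0].context_seq) < 60
        db = ReferenceDB(loci={loci[0].locus_id: loci[0]})
        write_reference(db, tmp_path / "r.fa", tmp_path / "r.tsv")
        back = read_reference(tmp_path / "r.fa", tmp_path / "r.tsv")
        assert back.loci[loci[0].locus_id].truncated

    def test_empty_db_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_reference(ReferenceDB(), tmp_path / "r.fa", tmp_path / "r.tsv")


def test_count_conservation(small_cohort):
    """Every planted run appears in exactly one locus per region class."""
    truth = small_cohort.ref.truth
    db_ids = set(small_cohort.ref.db.loci)
    assert set(truth["locus_id"]) <= db_ids
    # and no catalog locus without a generating planted run
    assert db_ids == set(truth["locus_id"])
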