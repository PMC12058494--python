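"""Read intake: genotyping, junction overlap rule, SAM path, builtin matcher."""

import pytest

from msirna.ingest import (
    FLANK_MISMATCH,
    INTERRUPTED_RUN,
    TRUNCATED_RUN,
    SeedIndex,
    count_junction_read,
    coverage_summary,
    genotype_read,
    ingest_sam,
    match_reads_builtin,
)
from msirna.refdb import JunctionRef, MicrosatelliteLocus
from msirna.simdata import write_sam


def make_locus(left="GTCGTACGATCGTACGTAGCT", base="A", L=12, right="CGATCGTAGCTAGCTGATCGTACGTAG"):
    ctx = left + base * L + right
    return MicrosatelliteLocus(
        locus_id="g|c|100|A|12|utr3",
        gene_id="g",
        transcript_ids=["t"],
        region="utr3",
        repeat_base=base,
        ref_length=L,
        contig="c",
        start=99,
        end=99 + L,
        strand="+",
        context_seq=ctx,
        transcript_offset=len(left),
    )


class TestGenotypeRead:
    def test_deletion(self):
        m = make_locus()
        read = m.left_flank[-10:] + "A" * 10 + m.right_flank[:10]
        assert genotype_read(read, m) == (-2, None)

    def test_identity_read_is_reference_length(self):
        m = make_locus()
        assert genotype_read(m.context_seq, m) == (0, None)

    def test_run_abutting_read_end_truncated(self):
        m = make_locus()
        read = m.left_flank[-10:] + "A" * 12  # no right anchor
        delta, reason = genotype_read(read, m)
        assert delta is None and reason == TRUNCATED_RUN

    def test_interrupted_run_rejected(self):
        m = make_locus()
        read = m.left_flank[-10:] + "A" * 5 + "G" + "A" * 6 + m.right_flank[:10]
        delta, reason = genotype_read(read, m)
        assert delta is None and reason == INTERRUPTED_RUN

    def test_flank_mismatch_counted(self):
        m = make_locus()
        read = m.left_flank[-8:] + "A" * 12 + "GGGCCGGGCC"
        delta, reason = genotype_read(read, m)
        assert delta is None and reason in (FLANK_MISMATCH, INTERRUPTED_RUN)

    def test_mismatch_tolerance(self):
        m = make_locus()
        left = list(m.left_flank[-10:])
        left[0] = "A" if left[0] != "A" else "C"
        left[2] = "G" if left[2] != "G" else "C"
        read = "".join(left) + "A" * 12 + m.right_flank[:10]
        assert genotype_read(read, m, max_mismatch=2) == (0, None)
        assert genotype_read(read, m, max_mismatch=1)[0] is None

    def test_genotype_agrees_with_scanner_oracle(self, small_cohort):
        """Accepted delta always equals (scanned read run length) - L(m)."""
        from msirna.refdb import scan_homopolymers

        sample = small_cohort.samples[0]
        db = small_cohort.ref.db
        checked = 0
        for lid, locus in db.loci.items():
            for _name, seq in sample.reads[:400]:
                delta, _ = genotype_read(seq, locus)
                if delta is None:
                    continue
                runs = [r for r in scan_homopolymers(seq, 1) if r[1] == locus.repeat_base]
                assert any(r[2] - locus.ref_length == delta for r in runs)
                checked += 1
        assert checked > 50


def make_junction(left, right, kind="expected"):
    return JunctionRef(
        junction_id=f"t|skipx1|{kind}",
        pair_id="t|skipx1",
        kind=kind,
        gene_id="g",
        transcript_id="t",
        left_seq=left,
        right_seq=right,
        skipped_exon_index=1,
        linked_locus_id="m",
        site="acceptor",
        site_distance_bp=2,
    )


class TestJunctionOverlap:
    left = "GATCGTACGTAGCTAGCTAGCTAGGATCC"[:29] + "T"  # 30 nt
    right = "CCTAGGCTAGCATCGATCGGATATCGCGAT"  # 30 nt

    def test_full_left_plus_eight(self):
        j = make_junction(self.left, self.right)
        assert count_junction_read(self.left + self.right[:8], j)

    def test_full_left_plus_seven_rejected(self):
        j = make_junction(self.left, self.right)
        assert not count_junction_read(self.left + self.right[:7], j)

    def test_full_right_plus_eight(self):
        j = make_junction(self.left, self.right)
        assert count_junction_read(self.left[-8:] + self.right, j)

    def test_read_inside_one_side_rejected(self):
        j = make_junction(self.left, self.right)
        assert not count_junction_read(self.left[:25], j)

    def test_partial_both_sides_rejected(self):
        j = make_junction(self.left, self.right)
        assert not count_junction_read(self.left[5:] + self.right[:20], j)


class TestIngestSam:
    def test_mapq_filter_and_monotonicity(self, small_cohort, tmp_path):
        sample = small_cohort.samples[0]
        db = small_cohort.ref.db
        sam = tmp_path / "s.sam"
        write_sam(sample, db, sam)
        n60 = sum(h.N for h in ingest_sam(sam, db, mapq_min=30).histograms.values())
        n61 = sum(h.N for h in ingest_sam(sam, db, mapq_min=61).histograms.values())
        assert n60 > 0 and n61 == 0  # simulated mapq is 60 throughout

    def test_mixed_mapq(self, small_cohort, tmp_path):
        sample = small_cohort.samples[0]
        db = small_cohort.ref.db
        lid = sorted(db.loci)[0]
        lines = [ln for ln in sample.sam_lines if f"\t{lid}\t" in ln]
        # degrade mapq of 40% of this locus's alignments below the floor
        k = int(0.4 * len(lines))
        degraded = [ln.replace("\t60\t", "\t10\t", 1) if i < k else ln for i, ln in enumerate(lines)]
        sam = tmp_path / "m.sam"
        with open(sam, "w") as fh:
            fh.write("@HD\tVN:1.6\n")
            fh.write(f"@SQ\tSN:{lid}\tLN:{len(db.loci[lid].context_seq)}\n")
            fh.write("\n".join(degraded) + "\n")
        res = ingest_sam(sam, db)
        assert res.histograms[lid].N == len(lines) - k
        assert res.rejected.get("mapq") == k

    def test_unknown_reference_skipped(self, small_cohort, tmp_path):
        db = small_cohort.ref.db
        sam = tmp_path / "u.sam"
        with open(sam, "w") as fh:
            fh.write("@HD\tVN:1.6\n@SQ\tSN:ghost\tLN:60\n")
            fh.write("r1\t0\tghost\t1\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t*\n")
        res = ingest_sam(sam, db)
        assert res.n_unassigned == 1 and res.n_accepted == 0


class TestBuiltinMatcher:
    def test_path_equivalence_zero_error(self, small_cohort, tmp_path):
        """SAM intake and the builtin matcher agree exactly on clean reads."""
        db = small_cohort.ref.db
        for sample in small_cohort.samples[:2]:
            sam = tmp_path / f"{sample.sample_id}.sam"
            write_sam(sample, db, sam)
            via_sam = ingest_sam(sam, db)
            via_matcher = match_reads_builtin(sample.reads, db)
            for lid in db.loci:
                assert via_sam.histograms[lid].counts == via_matcher.histograms[lid].counts
            for pid in via_sam.junction_counts:
                a, b = via_sam.junction_counts[pid], via_matcher.junction_counts[pid]
                assert (a.r_expected, a.r_skip) == (b.r_expected, b.r_skip)

    def test_random_read_unassigned(self, small_cohort):
        db = small_cohort.ref.db
        res = match_reads_builtin([("r", "ACGT" * 12 + "AC")], db)
        assert res.n_unassigned == 1 and res.n_accepted == 0

    def test_three_flank_mismatches_not_counted(self, small_cohort):
        db = small_cohort.ref.db
        lid = sorted(db.loci)[0]
        m = db.loci[lid]
        left = list(m.left_flank[-15:])
        for i in (0, 5, 9):
            left[i] = next(b for b in "ACGT" if b != left[i] and b != m.repeat_base)
        read = "".join(left) + m.repeat_base * m.ref_length + m.right_flank[: 35 - m.ref_length]
        res = match_reads_builtin([("r", read)], db, max_mismatch=2)
        assert res.histograms[lid].N == 0

    def test_seed_len_exceeding_flanks_errors(self, small_cohort):
        with pytest.raises(ValueError, match="seed_len"):
            SeedIndex(small_cohort.ref.db, seed_len=40)

    def test_conservation(self, small_cohort):
        db = small_cohort.ref.db
        sample = small_cohort.samples[0]
        noise = [(f"n{i}", "ACGTACGTACGTACGTACGTAC" * 2) for i in range(5)]
        res = match_reads_builtin(sample.reads + noise, db)
        assert (
            res.n_accepted + res.n_unassigned + sum(res.rejected.values())
            == res.n_considered
            == len(sample.reads) + 5
        )


def test_coverage_summary_boundaries():
    from msirna.ingest import LengthHistogram

    hists = {
        "a": LengthHistogram("a", 20, {0: 15}),
        "b": LengthHistogram("b", 20, {0: 14}),
        "c": LengthHistogram("c", 20, {0: 20}),
    }
    df = coverage_summary(hists, ["a", "b", "c", "d"]).set_index("locus_id")
    assert bool(df.loc["a", "expressed"]) is True  # N == 15 boundary
    assert bool(df.loc["b", "expressed"]) is False  # N == 14
    assert bool(df.loc["c", "mutated_support"]) is False  # all reference-length
    assert df.loc["d", "N"] == 0  # panel locus with no histogram
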