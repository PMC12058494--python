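"""Microsatellite reference database construction.

Scans annotated transcripts for mononucleotide microsatellites (homopolymer
runs of at least five identical bases), classifies each run by the region of
the transcript it falls in (coding, 5'/3' UTR, intron), and emits a custom
reference: one 60-bp sequence context per locus plus, for microsatellites
lying within 50 bp of a splice site, 30+30-bp exon-junction sequences for
both the expected splice and the single-exon-skip alternative.  RNA-seq reads
are later aligned (or matched) against this reference instead of the genome,
which keeps the downstream counting problem small.

Coordinates are 0-based half-open internally; everything written to the
catalog TSV is 1-based inclusive.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import contig_length, fetch, revcomp

CONTEXT_LEN = 60
JUNCTION_SIDE_LEN = 30
SPLICE_WINDOW = 50
MIN_RUN_LEN = 5

REGIONS = ("coding", "utr5", "utr3", "intron")


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript.

    ``exons`` are genomic 0-based half-open intervals in ascending genomic
    order; transcript order is ascending for ``+`` and descending for ``-``.
    ``cds`` is the genomic span of the coding sequence, or None for
    non-coding transcripts.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for (a0, a1), (b0, b1) in zip(self.exons, self.exons[1:]):
            if b0 < a1:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exons_transcript_order(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else self.exons[::-1]

    def region_of(self, pos: int) -> str | None:
        """Region class of a genomic position, or None outside the span."""
        s, e = self.span
        if not s <= pos < e:
            return None
        in_exon = any(a <= pos < b for a, b in self.exons)
        if not in_exon:
            return "intron"
        if self.cds is None:
            return None  # non-coding transcripts carry no region vocabulary
        c0, c1 = self.cds
        if c0 <= pos < c1:
            return "coding"
        if pos < c0:
            return "utr5" if self.strand == "+" else "utr3"
        return "utr3" if self.strand == "+" else "utr5"


@dataclass
class MicrosatelliteLocus:
    """One mononucleotide repeat with its sequence context.

    ``repeat_base`` and ``context_seq`` are in transcript orientation;
    ``start``/``end`` are the genomic 0-based half-open coordinates of the
    run on the forward strand.  ``transcript_offset`` is the 0-based position
    of the run inside ``context_seq``.
    """

    locus_id: str
    gene_id: str
    transcript_ids: list[str]
    region: str
    repeat_base: str
    ref_length: int
    contig: str
    start: int
    end: int
    strand: str
    context_seq: str
    transcript_offset: int
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.ref_length < 1:
            raise ValueError("ref_length must be positive")
        run = self.context_seq[
            self.transcript_offset : self.transcript_offset + self.ref_length
        ]
        if run != self.repeat_base * self.ref_length:
            raise ValueError(f"context of {self.locus_id} does not contain its run")

    @property
    def left_flank(self) -> str:
        return self.context_seq[: self.transcript_offset]

    @property
    def right_flank(self) -> str:
        return self.context_seq[self.transcript_offset + self.ref_length :]


@dataclass
class JunctionRef:
    """A 30+30-bp exon junction linked to a nearby microsatellite.

    ``kind`` is ``expected`` (splice joining the exons as annotated) or
    ``skip`` (the skipped-exon alternative).  Each skip junction has a paired
    expected junction over the same skipped exon, sharing ``pair_id``.
    """

    junction_id: str
    pair_id: str
    kind: str
    gene_id: str
    transcript_id: str
    left_seq: str
    right_seq: str
    skipped_exon_index: int
    linked_locus_id: str
    site: str
    site_distance_bp: int
    truncated: bool = False

    @property
    def seq(self) -> str:
        return self.left_seq + self.right_seq


@dataclass
class ReferenceDB:
    """The locus + junction catalog backing ingest and scoring."""

    loci: dict[str, MicrosatelliteLocus] = field(default_factory=dict)
    junctions: dict[str, JunctionRef] = field(default_factory=dict)

    def junction_pairs(self) -> dict[str, list[JunctionRef]]:
        pairs: dict[str, list[JunctionRef]] = {}
        for j in self.junctions.values():
            pairs.setdefault(j.pair_id, []).append(j)
        return pairs


def make_locus_id(
    gene_id: str, contig: str, start: int, base: str, length: int, region: str
) -> str:
    """Deterministic locus identifier; ``start`` is 0-based, emitted 1-based."""
    return f"{gene_id}|{contig}|{start + 1}|{base}|{length}|{region}"


def scan_homopolymers(
    seq: str, min_len: int = MIN_RUN_LEN
) -> list[tuple[int, str, int]]:
    """Find every maximal single-base run of length >= ``min_len``.

    Returns ``(start, base, run_length)`` tuples with 0-based starts, in
    coordinate order.  Runs of N are never reported; an interrupted run
    counts as two separate runs.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    seq = seq.upper()
    out: list[tuple[int, str, int]] = []
    i, n = 0, len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if seq[i] in "ACGT" and j - i >= min_len:
            out.append((i, seq[i], j - i))
        i = j
    return out


def _extract_context(
    genome, contig: str, run_start: int, run_end: int, strand: str
) -> tuple[str, int, bool]:
    """60-nt context centred on the run, in transcript orientation.

    Returns (context_seq, offset_of_run_in_context, truncated_flag).
    Contexts clipped at contig ends are kept but flagged.
    """
    length = run_end - run_start
    flank = max(CONTEXT_LEN - length, 0)
    # upstream flank (transcript orientation) gets the floor half
    up = flank // 2
    down = flank - up
    if strand == "+":
        want_left, want_right = up, down
    else:
        want_left, want_right = down, up
    clen = contig_length(genome, contig)
    c0 = max(0, run_start - want_left)
    c1 = min(clen, run_end + want_right)
    seq = fetch(genome, contig, c0, c1)
    truncated = len(seq) < min(CONTEXT_LEN, length + flank)
    if strand == "-":
        seq = revcomp(seq)
        offset = c1 - run_end
    else:
        offset = run_start - c0
    return seq, offset, truncated


def build_locus_db(
    transcripts: Iterable[TranscriptModel],
    genome,
    min_len: int = MIN_RUN_LEN,
) -> list[MicrosatelliteLocus]:
    """Scan transcript spans for homopolymer runs and build the locus catalog.

    One locus is produced per distinct genomic run x region class; isoforms
    sharing the same run and region are merged into a single locus carrying
    all transcript ids.  Sequence context is extracted in transcript
    orientation (reverse-complemented for ``-`` strand transcripts).
    Transcripts without a CDS are skipped: the region vocabulary is undefined
    for them.
    """
    merged: dict[tuple, MicrosatelliteLocus] = {}
    for t in transcripts:
        if t.cds is None:
            continue
        s, e = t.span
        if s < 0 or e > contig_length(genome, t.contig):
            raise ValueError(
                f"transcript {t.transcript_id} extends outside contig {t.contig}"
            )
        gseq = fetch(genome, t.contig, s, e)
        tseq = revcomp(gseq) if t.strand == "-" else gseq
        for t_start, base, length in scan_homopolymers(tseq, min_len):
            if t.strand == "+":
                g0 = s + t_start
            else:
                g0 = e - t_start - length
            g1 = g0 + length
            first_base_pos = g0 if t.strand == "+" else g1 - 1
            region = t.region_of(first_base_pos)
            if region is None:
                continue
            key = (t.gene_id, t.contig, g0, g1, t.strand, region)
            if key in merged:
                if t.transcript_id not in merged[key].transcript_ids:
                    merged[key].transcript_ids.append(t.transcript_id)
                continue
            ctx, offset, trunc = _extract_context(genome, t.contig, g0, g1, t.strand)
            merged[key] = MicrosatelliteLocus(
                locus_id=make_locus_id(t.gene_id, t.contig, g0, base, length, region),
                gene_id=t.gene_id,
                transcript_ids=[t.transcript_id],
                region=region,
                repeat_base=base,
                ref_length=length,
                contig=t.contig,
                start=g0,
                end=g1,
                strand=t.strand,
                context_seq=ctx,
                transcript_offset=offset,
                truncated=trunc,
            )
    return sorted(merged.values(), key=lambda m: m.locus_id)


def _exon_side_seq(genome, t: TranscriptModel, exon: tuple[int, int], side: str) -> str:
    """30 nt at the transcript-orientation 3' end ('tail') or 5' start ('head')."""
    a, b = exon
    n = min(JUNCTION_SIDE_LEN, b - a)
    if (side == "tail") == (t.strand == "+"):
        seq = fetch(genome, t.contig, b - n, b)
    else:
        seq = fetch(genome, t.contig, a, a + n)
    return revcomp(seq) if t.strand == "-" else seq


def build_junction_refs(
    transcript: TranscriptModel,
    loci: Iterable[MicrosatelliteLocus],
    genome,
    window: int = SPLICE_WINDOW,
) -> list[JunctionRef]:
    """Junction references for exons with an intronic microsatellite near a splice site.

    For each exon e_k (transcript order) whose acceptor site has an intronic
    run ending within ``window`` bp upstream, or whose donor site has one
    starting within ``window`` bp downstream (intronic side), emit the
    expected junction e_{k-1}|e_k and, when e_k is internal, the skip
    junction e_{k-1}|e_{k+1}.  Transcripts with fewer than three exons can
    only yield expected junctions.
    """
    t = transcript
    exons = t.exons_transcript_order
    n = len(exons)
    if n < 2:
        return []
    cand = [
        m
        for m in loci
        if m.region == "intron" and m.contig == t.contig and m.gene_id == t.gene_id
    ]
    out: list[JunctionRef] = []
    for k in range(1, n):  # expected junction needs an upstream exon
        hits: list[tuple[int, str, MicrosatelliteLocus]] = []
        ek = exons[k]
        # acceptor: intron upstream of e_k in transcript orientation
        for m in cand:
            if t.strand == "+":
                d_acc = ek[0] - m.end
            else:
                d_acc = m.start - ek[1]
            if 0 <= d_acc <= window:
                hits.append((d_acc, "acceptor", m))
        # donor: intron downstream of e_k (only exists for internal exons)
        if k < n - 1:
            for m in cand:
                if t.strand == "+":
                    d_don = m.start - ek[1]
                else:
                    d_don = ek[0] - m.end
                if 0 <= d_don <= window:
                    hits.append((d_don, "donor", m))
        if not hits:
            continue
        dist, site, locus = min(hits, key=lambda h: (h[0], h[1], h[2].locus_id))
        pair_id = f"{t.transcript_id}|skipx{k}"
        left = _exon_side_seq(genome, t, exons[k - 1], "tail")
        right_exp = _exon_side_seq(genome, t, ek, "head")
        trunc_exp = len(left) < JUNCTION_SIDE_LEN or len(right_exp) < JUNCTION_SIDE_LEN
        out.append(
            JunctionRef(
                junction_id=f"{pair_id}|expected",
                pair_id=pair_id,
                kind="expected",
                gene_id=t.gene_id,
                transcript_id=t.transcript_id,
                left_seq=left,
                right_seq=right_exp,
                skipped_exon_index=k,
                linked_locus_id=locus.locus_id,
                site=site,
                site_distance_bp=dist,
                truncated=trunc_exp,
            )
        )
        if k < n - 1:
            right_skip = _exon_side_seq(genome, t, exons[k + 1], "head")
            out.append(
                JunctionRef(
                    junction_id=f"{pair_id}|skip",
                    pair_id=pair_id,
                    kind="skip",
                    gene_id=t.gene_id,
                    transcript_id=t.transcript_id,
                    left_seq=left,
                    right_seq=right_skip,
                    skipped_exon_index=k,
                    linked_locus_id=locus.locus_id,
                    site=site,
                    site_distance_bp=dist,
                    truncated=len(left) < JUNCTION_SIDE_LEN
                    or len(right_skip) < JUNCTION_SIDE_LEN,
                )
            )
    return out


def build_reference_db(
    transcripts: Iterable[TranscriptModel],
    genome,
    min_len: int = MIN_RUN_LEN,
    window: int = SPLICE_WINDOW,
) -> ReferenceDB:
    """Convenience wrapper: loci plus junction refs for every transcript."""
    transcripts = list(transcripts)
    loci = build_locus_db(transcripts, genome, min_len=min_len)
    db = ReferenceDB(loci={m.locus_id: m for m in loci})
    seen: set[str] = set()
    for t in transcripts:
        for j in build_junction_refs(t, loci, genome, window=window):
            if j.junction_id in seen:
                continue
            seen.add(j.junction_id)
            db.junctions[j.junction_id] = j
    return db


_CATALOG_COLS = [
    "record_id",
    "kind",
    "gene_id",
    "transcript_ids",
    "region",
    "repeat_base",
    "ref_length",
    "contig",
    "start",
    "end",
    "strand",
    "transcript_offset",
    "truncated",
    "pair_id",
    "linked_locus_id",
    "site",
    "site_distance_bp",
    "left_len",
    "skipped_exon_index",
]


def write_reference(db: ReferenceDB, fasta_path, catalog_path) -> None:
    """Emit the reference FASTA and its catalog TSV (1-based coordinates)."""
    if not db.loci and not db.junctions:
        raise ValueError("empty reference database")
    records = []
    rows = []
    for m in sorted(db.loci.values(), key=lambda x: x.locus_id):
        records.append(SeqRecord(Seq(m.context_seq), id=m.locus_id, description=""))
        rows.append(
            {
                "record_id": m.locus_id,
                "kind": "locus",
                "gene_id": m.gene_id,
                "transcript_ids": ";".join(m.transcript_ids),
                "region": m.region,
                "repeat_base": m.repeat_base,
                "ref_length": m.ref_length,
                "contig": m.contig,
                "start": m.start + 1,
                "end": m.end,
                "strand": m.strand,
                "transcript_offset": m.transcript_offset + 1,
                "truncated": int(m.truncated),
                "pair_id": "",
                "linked_locus_id": "",
                "site": "",
                "site_distance_bp": "",
                "left_len": "",
                "skipped_exon_index": "",
            }
        )
    for j in sorted(db.junctions.values(), key=lambda x: x.junction_id):
        records.append(SeqRecord(Seq(j.seq), id=j.junction_id, description=""))
        rows.append(
            {
                "record_id": j.junction_id,
                "kind": f"junction_{j.kind}",
                "gene_id": j.gene_id,
                "transcript_ids": j.transcript_id,
                "region": "",
                "repeat_base": "",
                "ref_length": "",
                "contig": "",
                "start": "",
                "end": "",
                "strand": "",
                "transcript_offset": "",
                "truncated": int(j.truncated),
                "pair_id": j.pair_id,
                "linked_locus_id": j.linked_locus_id,
                "site": j.site,
                "site_distance_bp": j.site_distance_bp,
                "left_len": len(j.left_seq),
                "skipped_exon_index": j.skipped_exon_index,
            }
        )
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(catalog_path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=_CATALOG_COLS, delimiter="\t")
        w.writeheader()
        w.writerows(rows)


def read_reference(fasta_path, catalog_path) -> ReferenceDB:
    """Load a database previously written by :func:`write_reference`."""
    seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    db = ReferenceDB()
    with open(catalog_path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rid = row["record_id"]
            seq = seqs[rid]
            if row["kind"] == "locus":
                db.loci[rid] = MicrosatelliteLocus(
                    locus_id=rid,
                    gene_id=row["gene_id"],
                    transcript_ids=row["transcript_ids"].split(";"),
                    region=row["region"],
                    repeat_base=row["repeat_base"],
                    ref_length=int(row["ref_length"]),
                    contig=row["contig"],
                    start=int(row["start"]) - 1,
                    end=int(row["end"]),
                    strand=row["strand"],
                    context_seq=seq,
                    transcript_offset=int(row["transcript_offset"]) - 1,
                    truncated=bool(int(row["truncated"])),
                )
            else:
                left_len = int(row["left_len"])
                db.junctions[rid] = JunctionRef(
                    junction_id=rid,
                    pair_id=row["pair_id"],
                    kind=row["kind"].removeprefix("junction_"),
                    gene_id=row["gene_id"],
                    transcript_id=row["transcript_ids"],
                    left_seq=seq[:left_len],
                    right_seq=seq[left_len:],
                    skipped_exon_index=int(row["skipped_exon_index"]),
                    linked_locus_id=row["linked_locus_id"],
                    site=row["site"],
                    site_distance_bp=int(row["site_distance_bp"]),
                    truncated=bool(int(row["truncated"])),
                )
    return db


def load_transcripts_gtf(gtf_path) -> list[TranscriptModel]:
    """Parse exon/CDS features from a GTF (or GFF3) file into transcript models."""
    import gffutils

    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes.get("transcript_id", [feat.id])[0]
        gid = feat.attributes.get("gene_id", [tid])[0]
        rec = exons.setdefault(
            tid,
            {"gene": gid, "contig": feat.seqid, "strand": feat.strand, "exons": [], "cds": []},
        )
        iv = (feat.start - 1, feat.end)  # gffutils is 1-based inclusive
        if feat.featuretype == "exon":
            rec["exons"].append(iv)
        else:
            rec["cds"].append(iv)
    out = []
    for tid, rec in sorted(exons.items()):
        cds = None
        if rec["cds"]:
            cds = (min(a for a, _ in rec["cds"]), max(b for _, b in rec["cds"]))
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene"],
                contig=rec["contig"],
                strand=rec["strand"],
                exons=rec["exons"],
                cds=cds,
            )
        )
    return out
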