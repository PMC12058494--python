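"""Read ingest: per-locus length histograms and per-junction counts.

Two intake paths produce identical outputs on clean data: :func:`ingest_sam`
consumes alignments made against the emitted reference FASTA (e.g. by an
external aligner), while :func:`match_reads_builtin` assigns raw FASTQ reads
to reference entries with an exact-seed k-mer index, removing the external
aligner dependency.  Both paths share the same genotyping and
junction-overlap contracts:

* a read contributes to a locus histogram only if it contains the *entire*
  homopolymer run plus at least one matching non-repeat anchor base on each
  side; the observed run must be pure (an interrupted run is rejected);
* a read supports a junction only if it covers one full 30-nt side and at
  least 8 nt of the other side, contiguously across the junction point;
* alignments below the mapping-quality floor (default 30) are discarded
  before genotyping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd
import pysam

from ._util import revcomp
from .refdb import JunctionRef, MicrosatelliteLocus, ReferenceDB, scan_homopolymers

DEFAULT_MAPQ_MIN = 30
DEFAULT_MIN_OTHER_SIDE = 8
DEFAULT_SEED_LEN = 16
DEFAULT_MAX_MISMATCH = 2

#: typed genotyping rejection reasons
TRUNCATED_RUN = "truncated_run"
INTERRUPTED_RUN = "interrupted_run"
FLANK_MISMATCH = "flank_mismatch"
NO_JUNCTION_SPAN = "no_junction_span"


@dataclass
class LengthHistogram:
    """Read counts r_i indexed by length offset i relative to L(m)."""

    locus_id: str
    ref_length: int
    counts: dict[int, int] = field(default_factory=dict)

    @property
    def N(self) -> int:
        return sum(self.counts.values())

    @property
    def mutant_reads(self) -> int:
        return sum(r for i, r in self.counts.items() if i != 0)

    def add(self, delta: int, n: int = 1) -> None:
        self.counts[delta] = self.counts.get(delta, 0) + n


@dataclass
class JunctionCounts:
    """Spanning-read counts for one expected/skip junction pair."""

    pair_id: str
    linked_locus_id: str
    r_expected: int = 0
    r_skip: int = 0

    @property
    def total(self) -> int:
        return self.r_expected + self.r_skip


@dataclass
class IngestResult:
    histograms: dict[str, LengthHistogram]
    junction_counts: dict[str, JunctionCounts]
    n_considered: int = 0
    n_unassigned: int = 0
    rejected: dict[str, int] = field(default_factory=dict)

    @property
    def n_accepted(self) -> int:
        return sum(h.N for h in self.histograms.values()) + sum(
            j.total for j in self.junction_counts.values()
        )


def _empty_result(db: ReferenceDB) -> IngestResult:
    hists = {
        m.locus_id: LengthHistogram(m.locus_id, m.ref_length)
        for m in db.loci.values()
    }
    jcs = {}
    for pair_id, members in db.junction_pairs().items():
        jcs[pair_id] = JunctionCounts(pair_id, members[0].linked_locus_id)
    return IngestResult(hists, jcs)


def genotype_read(
    read_seq: str,
    locus: MicrosatelliteLocus,
    max_mismatch: int = 0,
) -> tuple[int | None, str | None]:
    """Measure the homopolymer length carried by a read.

    Returns ``(delta_i, None)`` where ``delta_i`` is observed run length
    minus L(m), or ``(None, reason)`` with a typed rejection.  The read's
    flanks are compared to the locus context flanks over their overlap, with
    at most ``max_mismatch`` mismatches in total, and the bases immediately
    adjacent to the run must match on both sides.
    """
    read = read_seq.upper()
    base = locus.repeat_base
    lf, rf = locus.left_flank, locus.right_flank
    best_reject = FLANK_MISMATCH if base in read else TRUNCATED_RUN
    saw_any_run = False
    # maximal runs of the repeat base in the read
    i, n = 0, len(read)
    while i < n:
        if read[i] != base:
            i += 1
            continue
        j = i
        while j < n and read[j] == base:
            j += 1
        saw_any_run = True
        if i == 0 or j == n:
            best_reject = TRUNCATED_RUN
            i = j
            continue
        llen = min(i, len(lf))
        rlen = min(n - j, len(rf))
        if llen < 1 or rlen < 1:
            best_reject = TRUNCATED_RUN
            i = j
            continue
        # anchor bases adjacent to the run must match exactly
        if read[i - 1] != lf[-1] or read[j] != rf[0]:
            if read[j] != rf[0] and base in read[j + 1 :]:
                best_reject = INTERRUPTED_RUN
            i = j
            continue
        mism = sum(
            1 for a, b in zip(read[i - llen : i], lf[-llen:]) if a != b
        ) + sum(1 for a, b in zip(read[j : j + rlen], rf[:rlen]) if a != b)
        if mism <= max_mismatch:
            return j - i - locus.ref_length, None
        best_reject = FLANK_MISMATCH
        i = j
    if not saw_any_run:
        best_reject = FLANK_MISMATCH
    return None, best_reject


def count_junction_read(
    read_seq: str,
    junction: JunctionRef,
    min_other_side: int = DEFAULT_MIN_OTHER_SIDE,
    max_mismatch: int = 0,
) -> bool:
    """True if the read spans the junction per the full-side + 8-bp rule."""
    read = read_seq.upper()
    ref = junction.seq
    jpoint = len(junction.left_seq)
    if len(read) > len(ref):
        return False
    best = None
    for s in range(len(ref) - len(read) + 1):
        mism = sum(1 for a, b in zip(read, ref[s : s + len(read)]) if a != b)
        if mism <= max_mismatch and (best is None or mism < best[1]):
            best = (s, mism)
    if best is None:
        return False
    s = best[0]
    e = s + len(read)
    left_cov = max(0, min(e, jpoint) - s)
    right_cov = max(0, e - max(s, jpoint))
    full_left = s == 0 and left_cov == jpoint
    full_right = e == len(ref) and right_cov == len(junction.right_seq)
    if full_left and right_cov >= min_other_side:
        return True
    if full_right and left_cov >= min_other_side:
        return True
    return False


def _process_assignment(
    result: IngestResult,
    db: ReferenceDB,
    target: str,
    seq: str,
    min_other_side: int,
    max_mismatch: int,
) -> None:
    if target in db.loci:
        delta, reason = genotype_read(seq, db.loci[target], max_mismatch=max_mismatch)
        if delta is not None:
            result.histograms[target].add(delta)
        else:
            result.rejected[reason] = result.rejected.get(reason, 0) + 1
        return
    j = db.junctions[target]
    if count_junction_read(seq, j, min_other_side=min_other_side, max_mismatch=max_mismatch):
        jc = result.junction_counts[j.pair_id]
        if j.kind == "skip":
            jc.r_skip += 1
        else:
            jc.r_expected += 1
    else:
        result.rejected[NO_JUNCTION_SPAN] = result.rejected.get(NO_JUNCTION_SPAN, 0) + 1


def ingest_sam(
    sam_path,
    db: ReferenceDB,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    min_other_side: int = DEFAULT_MIN_OTHER_SIDE,
    max_mismatch: int = 0,
) -> IngestResult:
    """Count alignments made against the emitted reference FASTA.

    Secondary and supplementary alignments are ignored; alignments with
    mapq below ``mapq_min`` are discarded before genotyping.  Alignments to
    reference names absent from the catalog are skipped.  Duplicate read
    names are processed independently (RNA-seq duplicates carry signal).
    """
    result = _empty_result(db)
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            result.n_considered += 1
            if aln.mapping_quality < mapq_min:
                result.rejected["mapq"] = result.rejected.get("mapq", 0) + 1
                continue
            target = aln.reference_name
            if target not in db.loci and target not in db.junctions:
                result.n_unassigned += 1
                continue
            seq = aln.query_sequence
            if seq is None:
                result.n_unassigned += 1
                continue
            if aln.is_reverse:
                # query_sequence is already reported on the reference strand
                pass
            _process_assignment(result, db, target, seq, min_other_side, max_mismatch)
    return result


class SeedIndex:
    """Exact k-mer index over flank-anchored reference windows.

    Seeds for locus entries are every context k-mer containing at least one
    non-repeat flank base (a k-mer wholly inside a long homopolymer is
    uninformative and shared between loci); k-mers crossing the flank/run
    boundary keep reads matchable even when a long run squeezes both pure
    flank segments below ``seed_len``.  Junction entries contribute k-mers
    over their whole sequence.
    """

    def __init__(self, db: ReferenceDB, seed_len: int = DEFAULT_SEED_LEN):
        if seed_len < 4:
            raise ValueError("seed_len must be >= 4")
        self.db = db
        self.seed_len = seed_len
        self.index: dict[str, set[str]] = {}
        for m in db.loci.values():
            if seed_len > max(len(m.left_flank), len(m.right_flank)):
                raise ValueError(
                    f"seed_len={seed_len} exceeds both flanks of locus {m.locus_id}"
                )
            run0 = m.transcript_offset
            run1 = run0 + m.ref_length
            self._add_windows(
                m.locus_id,
                m.context_seq,
                skip=lambda i, k=seed_len: run0 <= i and i + k <= run1,
            )
        for j in db.junctions.values():
            if self._add_windows(j.junction_id, j.seq) == 0:
                raise ValueError(
                    f"seed_len={seed_len} exceeds junction {j.junction_id}"
                )

    def _add_windows(self, entry_id: str, seq: str, skip=None) -> int:
        k = self.seed_len
        n = 0
        for i in range(len(seq) - k + 1):
            if skip is not None and skip(i):
                continue
            self.index.setdefault(seq[i : i + k], set()).add(entry_id)
            n += 1
        return n

    def candidates(self, read: str) -> set[str]:
        k = self.seed_len
        out: set[str] = set()
        for i in range(len(read) - k + 1):
            out |= self.index.get(read[i : i + k], set())
        return out


def _verify(
    db: ReferenceDB,
    target: str,
    seq: str,
    min_other_side: int,
    max_mismatch: int,
) -> tuple[bool, int | None, str | None]:
    """(accepted, delta_for_locus, rejection_reason)."""
    if target in db.loci:
        delta, reason = genotype_read(seq, db.loci[target], max_mismatch=max_mismatch)
        return delta is not None, delta, reason
    ok = count_junction_read(
        seq, db.junctions[target], min_other_side=min_other_side, max_mismatch=max_mismatch
    )
    return ok, None, None if ok else NO_JUNCTION_SPAN


def iter_fastq(fastq) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) from a FASTQ path or an iterable of tuples."""
    if isinstance(fastq, (str, bytes)) or hasattr(fastq, "__fspath__"):
        with pysam.FastxFile(str(fastq)) as fh:
            for rec in fh:
                yield rec.name, rec.sequence
    else:
        for item in fastq:
            if isinstance(item, tuple):
                yield item[0], item[1]
            else:
                yield item.name, item.sequence


def match_reads_builtin(
    fastq,
    db: ReferenceDB,
    seed_len: int = DEFAULT_SEED_LEN,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    min_other_side: int = DEFAULT_MIN_OTHER_SIDE,
) -> IngestResult:
    """Aligner-free intake: seed k-mer assignment + the shared verification rules.

    Each read (either orientation) is matched against candidate reference
    entries sharing an exact ``seed_len``-mer with it; candidates are then
    verified with :func:`genotype_read` / :func:`count_junction_read`.  A
    read verifying against more than one entry is dropped as ambiguous,
    mirroring the mapq filter's intent.  Deterministic for fixed inputs.
    """
    idx = SeedIndex(db, seed_len=seed_len)
    result = _empty_result(db)
    for _name, seq in iter_fastq(fastq):
        result.n_considered += 1
        seq = seq.upper()
        accepted: list[tuple[str, str, int | None]] = []
        reasons: list[str] = []
        seen: set[tuple[str, str]] = set()
        for oriented in (seq, revcomp(seq)):
            for target in idx.candidates(oriented):
                if (target, oriented) in seen:
                    continue
                seen.add((target, oriented))
                ok, delta, reason = _verify(
                    db, target, oriented, min_other_side, max_mismatch
                )
                if ok:
                    accepted.append((target, oriented, delta))
                elif reason is not None:
                    reasons.append(reason)
        # the same physical entry may verify in one orientation only; >1
        # distinct entries accepting the read is an ambiguity -> drop
        entries = {t for t, _, _ in accepted}
        if len(entries) == 1:
            target, oriented, delta = accepted[0]
            if target in db.loci:
                result.histograms[target].add(delta)
            else:
                j = db.junctions[target]
                jc = result.junction_counts[j.pair_id]
                if j.kind == "skip":
                    jc.r_skip += 1
                else:
                    jc.r_expected += 1
        elif len(entries) > 1:
            result.rejected["ambiguous"] = result.rejected.get("ambiguous", 0) + 1
        elif reasons:
            reason = reasons[0]
            result.rejected[reason] = result.rejected.get(reason, 0) + 1
        else:
            result.n_unassigned += 1
    return result


def coverage_summary(
    histograms: dict[str, LengthHistogram],
    panel: Iterable[str] | None = None,
    expressed_min_cov: int = 15,
    mutated_min_reads: int = 5,
) -> pd.DataFrame:
    """Per-locus coverage table with expression / mutant-support flags.

    ``expressed`` requires coverage >= 15 only; the >= 5 mutated-read
    condition is kept as a separate ``mutated_support`` flag used for
    instability eligibility (see scoring).
    """
    ids = list(panel) if panel is not None else sorted(histograms)
    rows = []
    for lid in ids:
        h = histograms.get(lid)
        n = h.N if h else 0
        mut = h.mutant_reads if h else 0
        rows.append(
            {
                "locus_id": lid,
                "N": n,
                "mutant_reads": mut,
                "expressed": n >= expressed_min_cov,
                "mutated_support": mut >= mutated_min_reads,
            }
        )
    return pd.DataFrame(rows, columns=["locus_id", "N", "mutant_reads", "expressed", "mutated_support"])


def write_histograms_tsv(histograms: dict[str, LengthHistogram], path) -> None:
    """Persist histograms as TSV (locus_id, ref_length, offset i, r_i) for rescoring."""
    rows = []
    for lid in sorted(histograms):
        h = histograms[lid]
        for i in sorted(h.counts):
            rows.append((lid, h.ref_length, i, h.counts[i]))
    with open(path, "w") as fh:
        fh.write("locus_id\tref_length\ti\tr_i\n")
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")


def read_histograms_tsv(path) -> dict[str, LengthHistogram]:
    out: dict[str, LengthHistogram] = {}
    df = pd.read_csv(path, sep="\t")
    for row in df.itertuples(index=False):
        h = out.setdefault(row.locus_id, LengthHistogram(row.locus_id, int(row.ref_length)))
        h.add(int(row.i), int(row.r_i))
    return out


def write_junction_counts_tsv(jcs: dict[str, JunctionCounts], path) -> None:
    with open(path, "w") as fh:
        fh.write("pair_id\tlinked_locus_id\tr_expected\tr_skip\n")
        for pid in sorted(jcs):
            j = jcs[pid]
            fh.write(f"{pid}\t{j.linked_locus_id}\t{j.r_expected}\t{j.r_skip}\n")


def read_junction_counts_tsv(path) -> dict[str, JunctionCounts]:
    df = pd.read_csv(path, sep="\t")
    return {
        row.pair_id: JunctionCounts(
            row.pair_id, row.linked_locus_id, int(row.r_expected), int(row.r_skip)
        )
        for row in df.itertuples(index=False)
    }
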