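"""Mismatch-repair-deficiency (MMRd) estimation from relative MMR-gene expression.

Loss of expression of MLH1 or MSH2 (most often through MLH1 promoter
hypermethylation) is the dominant cause of MMR deficiency in MSI tumours.
Reads are counted against the spliced CDS sequences of MLH1, MSH2 and MSH6,
counts are divided by CDS length, and each gene's share of the normalized
total is compared to published drop-out thresholds: MMRd is called when
MLH1 or MSH2 falls below 15% or MSH6 below 10% of the normalized total.
In MMR-proficient samples each gene sits close to 35% (+/- 10%).  PMS2 is
excluded by default (its dysregulation is rare and its expression stays
high even in MSI-H samples) but the gene set follows whatever CDS FASTA is
supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio import SeqIO

from ._util import revcomp

DEFAULT_THRESHOLDS = {"MLH1": 15.0, "MSH2": 15.0, "MSH6": 10.0}
NORMAL_BAND = (25.0, 45.0)  # 35% +/- 10%
DEFAULT_MIN_TOTAL = 100
REQUIRED_GENES = ("MLH1", "MSH2", "MSH6")

VERDICT_PROFICIENT = "MMR+"
VERDICT_DEFICIENT = "MMRd"
VERDICT_UNDETERMINED = "undetermined"


@dataclass
class MMRExpression:
    """CDS-length-normalized relative expression and the MMRd verdict."""

    raw_counts: dict[str, int]
    cds_lengths: dict[str, int]
    relative_pct: dict[str, float] = field(default_factory=dict)
    verdict: str = VERDICT_UNDETERMINED
    deficient_genes: tuple[str, ...] = ()
    in_normal_band: bool = False


def load_cds(cds_fasta, required: Iterable[str] = REQUIRED_GENES) -> dict[str, str]:
    """Read the MMR CDS FASTA; record ids are gene names."""
    seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(cds_fasta), "fasta")}
    missing = [g for g in required if g not in seqs]
    if missing:
        raise ValueError(f"CDS reference is missing required genes: {missing}")
    return seqs


class _CDSIndex:
    """Minimal exact-seed read-to-gene assigner (same contract as ingest)."""

    def __init__(self, cds: Mapping[str, str], seed_len: int = 16):
        self.seed_len = seed_len
        self.index: dict[str, set[str]] = {}
        for gene, seq in cds.items():
            if len(seq) < seed_len:
                raise ValueError(f"CDS of {gene} shorter than seed_len")
            for i in range(len(seq) - seed_len + 1):
                self.index.setdefault(seq[i : i + seed_len], set()).add(gene)

    def assign(self, read: str) -> str | None:
        hits: set[str] = set()
        for oriented in (read, revcomp(read)):
            for i in range(len(oriented) - self.seed_len + 1):
                hits |= self.index.get(oriented[i : i + self.seed_len], set())
        return hits.pop() if len(hits) == 1 else None


def mmr_quantify(reads, cds_fasta, seed_len: int = 16) -> tuple[dict[str, int], dict[str, int]]:
    """Count reads per MMR gene against the spliced CDS reference.

    ``reads`` is a FASTQ path or an iterable of (name, sequence) pairs.
    Returns (raw_counts, cds_lengths); reads matching no gene, or more than
    one, are dropped.
    """
    from .ingest import iter_fastq

    cds = load_cds(cds_fasta)
    idx = _CDSIndex(cds, seed_len=seed_len)
    counts = {g: 0 for g in cds}
    for _name, seq in iter_fastq(reads):
        gene = idx.assign(seq.upper())
        if gene is not None:
            counts[gene] += 1
    return counts, {g: len(s) for g, s in cds.items()}


def mmr_call(
    raw_counts: Mapping[str, int],
    cds_lengths: Mapping[str, int],
    thresholds: Mapping[str, float] | None = None,
    min_total: int = DEFAULT_MIN_TOTAL,
) -> MMRExpression:
    """CDS-length normalization + threshold verdict.

    normalized_g = raw_g / cds_length_g; relative_pct_g = 100 * normalized_g
    / sum(normalized).  MMRd iff any thresholded gene drops strictly below
    its cutoff; fewer than ``min_total`` assigned reads yields undetermined.
    """
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    expr = MMRExpression(dict(raw_counts), dict(cds_lengths))
    total_reads = sum(raw_counts.values())
    if total_reads < min_total:
        return expr
    norm = {g: raw_counts[g] / cds_lengths[g] for g in raw_counts}
    tot = sum(norm.values())
    expr.relative_pct = {g: 100.0 * v / tot for g, v in norm.items()}
    deficient = tuple(
        g
        for g in sorted(thresholds)
        if g in expr.relative_pct and expr.relative_pct[g] < thresholds[g]
    )
    expr.deficient_genes = deficient
    expr.verdict = VERDICT_DEFICIENT if deficient else VERDICT_PROFICIENT
    lo, hi = NORMAL_BAND
    expr.in_normal_band = all(lo <= v <= hi for v in expr.relative_pct.values())
    return expr


def write_mmr_tsv(sample_id: str, expr: MMRExpression, path) -> None:
    genes = sorted(expr.raw_counts)
    with open(path, "w") as fh:
        cols = ["sample_id"]
        cols += [f"{g}_reads" for g in genes]
        cols += [f"{g}_pct" for g in genes]
        cols += ["verdict", "deficient_genes", "in_normal_band"]
        fh.write("\t".join(cols) + "\n")
        vals = [sample_id]
        vals += [str(expr.raw_counts[g]) for g in genes]
        vals += [
            f"{expr.relative_pct[g]:.3f}" if g in expr.relative_pct else "" for g in genes
        ]
        vals += [expr.verdict, ";".join(expr.deficient_genes), str(int(expr.in_normal_band))]
        fh.write("\t".join(vals) + "\n")
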