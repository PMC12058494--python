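"""Seeded synthetic data: toy annotations, panels and reads with planted slippage.

The generator emulates the polymerase-slippage picture of microsatellite
instability: in MSI-labelled samples a configurable fraction of reads over
each unstable locus carries a planted length offset (deletion-dominated,
magnitudes 1-3), while MSS samples show only a small background of
slippage-like offsets.  One gene mimics the classic exon-skipping driver
(a T17 intronic run ending 2 nt before the acceptor site of an internal
exon), and MMR CDS references with tunable per-gene expression let the
MMRd classifier be exercised end to end.

Defaults are the conditions used for end-to-end label recovery: a
100-locus 3'UTR panel (run lengths 15-25 nt), 50x per-locus coverage,
instability planted at 60% of the panel with mutant fraction 0.4, MSS
background 0.02, and 10 MSI + 10 MSS samples.  Reads (50 nt) are drawn
uniformly over start positions that keep the whole run plus at least one
anchor base on each side inside the read, so every read is genotypable at
zero error rate.  Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .refdb import ReferenceDB, TranscriptModel, build_reference_db, make_locus_id

BASES = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_panel_loci: int = 100  # 3'UTR panel
    n_coding_loci: int = 5
    n_intron_loci: int = 5
    n_utr5_loci: int = 1
    n_skip_genes: int = 1
    panel_len_range: tuple[int, int] = (15, 25)
    other_len_range: tuple[int, int] = (8, 12)
    coverage: float = 50.0
    junction_coverage: float = 60.0
    read_length: int = 50
    base_error_rate: float = 0.0
    msi_unstable_frac: float = 0.6
    mutant_fraction: float = 0.4
    mss_background: float = 0.02
    offset_max_magnitude: int = 3
    offset_geom_p: float = 0.5
    deletion_prob: float = 0.9
    skip_fraction: float = 0.3
    mss_skip_fraction: float = 0.0
    n_msi: int = 10
    n_mss: int = 10
    mmr_read_total: int = 300
    mmr_cds_lengths: tuple[tuple[str, int], ...] = (
        ("MLH1", 2271),
        ("MSH2", 2805),
        ("MSH6", 4083),
    )
    mmr_deficient_gene: str = "MLH1"
    mmr_deficient_level: float = 0.15

    def __post_init__(self) -> None:
        for name in (
            "msi_unstable_frac",
            "mutant_fraction",
            "mss_background",
            "skip_fraction",
            "mss_skip_fraction",
            "base_error_rate",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SimReference:
    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    db: ReferenceDB
    panel: list[str]
    truth: pd.DataFrame  # one row per planted locus
    mmr_cds: dict[str, str]


@dataclass
class SampleSim:
    sample_id: str
    label: str
    reads: list[tuple[str, str]]
    sam_lines: list[str]
    mmr_reads: list[tuple[str, str]]
    truth_histograms: dict[str, dict[int, int]]
    truth_junctions: dict[str, tuple[int, int]] = field(default_factory=dict)


def _background_seq(rng: np.random.Generator, n: int) -> list[str]:
    """Random sequence with no homopolymer run longer than 3 nt."""
    out: list[str] = []
    for _ in range(n):
        if len(out) >= 3 and out[-1] == out[-2] == out[-3]:
            choices = [b for b in BASES if b != out[-1]]
            out.append(choices[rng.integers(3)])
        else:
            out.append(BASES[rng.integers(4)])
    return out


def _plant_run(seq: list[str], start: int, base: str, length: int) -> None:
    """Write a maximal run into the sequence, fixing its boundary bases."""
    seq[start : start + length] = [base] * length
    for pos in (start - 1, start + length):
        if 0 <= pos < len(seq) and seq[pos] == base:
            seq[pos] = next(b for b in BASES if b != base and b != seq[pos])
    # re-break any accidental >=4 run created at the boundaries
    for pos in (start - 1, start + length):
        if 0 <= pos < len(seq):
            lo = max(0, pos - 3)
            window = seq[lo : pos + 4]
            for k in range(len(window) - 3):
                if len(set(window[k : k + 4])) == 1 and window[k] != base:
                    seq[lo + k + 1] = next(
                        b for b in BASES if b not in (window[k], base)
                    )


def simulate_reference(cfg: SimConfig) -> SimReference:
    """Build the toy genome, annotation, panel, MMR CDS and truth table."""
    rng = np.random.default_rng([cfg.seed, 11])
    genome: dict[str, str] = {}
    transcripts: list[TranscriptModel] = []
    truth_rows: list[dict] = []
    panel: list[str] = []

    def add_single_exon_gene(name: str, region: str, lrange: tuple[int, int]) -> None:
        contig = f"chr_{name}"
        gene = f"g_{name}"
        length = int(rng.integers(lrange[0], lrange[1] + 1))
        base = "AT"[rng.integers(2)] if region in ("utr3", "utr5") else BASES[rng.integers(4)]
        seq = _background_seq(rng, 500)
        # exon [100, 400); CDS and run placement depend on the region class
        if region == "utr3":
            cds = (100, 250)
            run_start = 310
        elif region == "utr5":
            cds = (250, 400)
            run_start = 150
        else:  # coding
            cds = (100, 400)
            run_start = 200
        _plant_run(seq, run_start, base, length)
        genome[contig] = "".join(seq)
        transcripts.append(
            TranscriptModel(f"t_{name}", gene, contig, "+", [(100, 400)], cds)
        )
        lid = make_locus_id(gene, contig, run_start, base, length, region)
        truth_rows.append(
            {
                "locus_id": lid,
                "gene_id": gene,
                "contig": contig,
                "start": run_start + 1,
                "repeat_base": base,
                "ref_length": length,
                "region": region,
                "in_panel": region == "utr3",
            }
        )
        if region == "utr3":
            panel.append(lid)

    for i in range(cfg.n_panel_loci):
        add_single_exon_gene(f"u3_{i:03d}", "utr3", cfg.panel_len_range)
    for i in range(cfg.n_utr5_loci):
        add_single_exon_gene(f"u5_{i:03d}", "utr5", cfg.other_len_range)
    for i in range(cfg.n_coding_loci):
        add_single_exon_gene(f"cd_{i:03d}", "coding", cfg.other_len_range)

    for i in range(cfg.n_intron_loci):
        # two-exon gene, run deep in the intron (>50 bp from both splice sites)
        contig = f"chr_in_{i:03d}"
        gene = f"g_in_{i:03d}"
        length = int(rng.integers(*cfg.other_len_range, endpoint=True))
        base = "AT"[rng.integers(2)]
        seq = _background_seq(rng, 540)
        _plant_run(seq, 260, base, length)
        genome[contig] = "".join(seq)
        transcripts.append(
            TranscriptModel(
                f"t_in_{i:03d}", gene, contig, "+", [(100, 200), (340, 440)], (100, 440)
            )
        )
        truth_rows.append(
            {
                "locus_id": make_locus_id(gene, contig, 260, base, length, "intron"),
                "gene_id": gene,
                "contig": contig,
                "start": 261,
                "repeat_base": base,
                "ref_length": length,
                "region": "intron",
                "in_panel": False,
            }
        )

    for i in range(cfg.n_skip_genes):
        # three-exon gene with a T17 run ending 2 nt before the internal
        # exon's acceptor site, mimicking the known exon-skipping driver
        contig = f"chr_sk_{i:03d}"
        gene = f"g_sk_{i:03d}"
        seq = _background_seq(rng, 660)
        _plant_run(seq, 281, "T", 17)  # run [281, 298); exon 2 starts at 300
        if seq[298] == "T":
            seq[298] = "C"
        if seq[299] == "T":
            seq[299] = "C"
        genome[contig] = "".join(seq)
        transcripts.append(
            TranscriptModel(
                f"t_sk_{i:03d}",
                gene,
                contig,
                "+",
                [(100, 160), (300, 340), (500, 560)],
                (100, 560),
            )
        )
        truth_rows.append(
            {
                "locus_id": make_locus_id(gene, contig, 281, "T", 17, "intron"),
                "gene_id": gene,
                "contig": contig,
                "start": 282,
                "repeat_base": "T",
                "ref_length": 17,
                "region": "intron",
                "in_panel": False,
            }
        )

    db = build_reference_db(transcripts, genome)
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "locus_id",
            "gene_id",
            "contig",
            "start",
            "repeat_base",
            "ref_length",
            "region",
            "in_panel",
        ],
    )

    # plant instability: a fraction of the panel plus every non-panel locus
    n_unstable = int(round(cfg.msi_unstable_frac * len(panel)))
    unstable_panel = set(
        rng.choice(np.array(panel, dtype=object), size=n_unstable, replace=False)
    ) if panel else set()
    offsets = {}
    for lid in truth["locus_id"]:
        if lid in unstable_panel or lid not in panel:
            offsets[lid] = _draw_offset(rng, cfg)
    truth["unstable_in_msi"] = truth["locus_id"].map(lambda x: x in offsets)
    truth["planted_offset"] = truth["locus_id"].map(lambda x: offsets.get(x, 0))

    mmr_cds = {
        g: "".join(_background_seq(rng, n)) for g, n in cfg.mmr_cds_lengths
    }
    return SimReference(genome, transcripts, db, panel, truth, mmr_cds)


def _draw_offset(rng: np.random.Generator, cfg: SimConfig) -> int:
    mag = min(int(rng.geometric(cfg.offset_geom_p)), cfg.offset_max_magnitude)
    sign = -1 if rng.random() < cfg.deletion_prob else 1
    return sign * mag


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            alts = [b for b in BASES if b != chars[i]]
            chars[i] = alts[int(rng.integers(3))]
    return "".join(chars)


def simulate_sample(
    ref: SimReference,
    cfg: SimConfig,
    label: str,
    sample_id: str,
    rng: np.random.Generator,
) -> SampleSim:
    """Draw reads for one sample; truth histograms track intended offsets."""
    if label not in ("MSI", "MSS"):
        raise ValueError("label must be MSI or MSS")
    planted = dict(zip(ref.truth["locus_id"], ref.truth["planted_offset"]))
    unstable = set(ref.truth.loc[ref.truth["unstable_in_msi"], "locus_id"])
    reads: list[tuple[str, str]] = []
    sam_lines: list[str] = []
    truth_h: dict[str, dict[int, int]] = {}
    counter = 0
    rl = cfg.read_length
    for lid in sorted(ref.db.loci):
        locus = ref.db.loci[lid]
        hist: dict[int, int] = {}
        n = int(rng.poisson(cfg.coverage))
        lf = locus.transcript_offset
        rf = len(locus.context_seq) - lf - locus.ref_length
        for _ in range(n):
            if label == "MSI" and lid in unstable:
                delta = planted[lid] if rng.random() < cfg.mutant_fraction else 0
            else:
                delta = _draw_offset(rng, cfg) if rng.random() < cfg.mss_background else 0
            k = locus.ref_length + delta
            if k < 1:
                delta, k = 0, locus.ref_length
            a_min = max(1, rl - k - rf)
            a_max = min(lf, rl - k - 1)
            if a_min > a_max:
                continue  # read too short for this run; skip silently
            a = int(rng.integers(a_min, a_max + 1))
            b = rl - k - a
            g0, g1 = locus.start, locus.end
            seq = (
                ref.genome[locus.contig][g0 - a : g0]
                + locus.repeat_base * k
                + ref.genome[locus.contig][g1 : g1 + b]
            )
            seq = _mutate(rng, seq, cfg.base_error_rate)
            name = f"{sample_id}:r{counter:06d}"
            counter += 1
            reads.append((name, seq))
            hist[delta] = hist.get(delta, 0) + 1
            pos = lf - a + 1
            if delta == 0:
                cigar = f"{rl}M"
            elif delta < 0:
                cigar = f"{a + k}M{-delta}D{b}M"
            else:
                cigar = f"{a + locus.ref_length}M{delta}I{b}M"
            sam_lines.append(
                f"{name}\t0\t{lid}\t{pos}\t60\t{cigar}\t*\t0\t0\t{seq}\t*"
            )
        truth_h[lid] = hist
    truth_j: dict[str, tuple[int, int]] = {}
    skip_p = cfg.skip_fraction if label == "MSI" else cfg.mss_skip_fraction
    for pair_id, members in sorted(ref.db.junction_pairs().items()):
        by_kind = {j.kind: j for j in members}
        if "expected" not in by_kind:
            continue
        n = int(rng.poisson(cfg.junction_coverage))
        r_e = r_s = 0
        for _ in range(n):
            is_skip = "skip" in by_kind and rng.random() < skip_p
            j = by_kind["skip"] if is_skip else by_kind["expected"]
            s = 0 if rng.random() < 0.5 else len(j.seq) - rl
            seq = _mutate(rng, j.seq[s : s + rl], cfg.base_error_rate)
            name = f"{sample_id}:r{counter:06d}"
            counter += 1
            reads.append((name, seq))
            sam_lines.append(
                f"{name}\t0\t{j.junction_id}\t{s + 1}\t60\t{rl}M\t*\t0\t0\t{seq}\t*"
            )
            if is_skip:
                r_s += 1
            else:
                r_e += 1
        truth_j[pair_id] = (r_e, r_s)
    mmr_reads = _simulate_mmr_reads(ref, cfg, label, sample_id, rng)
    return SampleSim(sample_id, label, reads, sam_lines, mmr_reads, truth_h, truth_j)


def _simulate_mmr_reads(
    ref: SimReference,
    cfg: SimConfig,
    label: str,
    sample_id: str,
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    genes = sorted(ref.mmr_cds)
    expr = {g: 1.0 for g in genes}
    if label == "MSI":
        expr[cfg.mmr_deficient_gene] = cfg.mmr_deficient_level
    weights = np.array([len(ref.mmr_cds[g]) * expr[g] for g in genes], dtype=float)
    counts = rng.multinomial(cfg.mmr_read_total, weights / weights.sum())
    out = []
    i = 0
    for g, n in zip(genes, counts):
        seq = ref.mmr_cds[g]
        for _ in range(int(n)):
            s = int(rng.integers(0, len(seq) - cfg.read_length + 1))
            out.append(
                (f"{sample_id}:mmr{i:05d}", _mutate(rng, seq[s : s + cfg.read_length], cfg.base_error_rate))
            )
            i += 1
    return out


@dataclass
class CohortSim:
    cfg: SimConfig
    ref: SimReference
    samples: list[SampleSim]


def simulate_cohort(cfg: SimConfig) -> CohortSim:
    """The full stated world: reference plus n_msi + n_mss seeded samples."""
    ref = simulate_reference(cfg)
    samples = []
    for i in range(cfg.n_msi):
        rng = np.random.default_rng([cfg.seed, 100 + i])
        samples.append(simulate_sample(ref, cfg, "MSI", f"msi_{i:02d}", rng))
    for i in range(cfg.n_mss):
        rng = np.random.default_rng([cfg.seed, 500 + i])
        samples.append(simulate_sample(ref, cfg, "MSS", f"mss_{i:02d}", rng))
    return CohortSim(cfg, ref, samples)


# ---------------------------------------------------------------------------
# writers


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), 70):
                fh.write(s[i : i + 70] + "\n")


def write_gtf(transcripts: list[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            for a, b in t.exons:
                fh.write(
                    f"{t.contig}\tsim\texon\t{a + 1}\t{b}\t.\t{t.strand}\t.\t{attrs}\n"
                )
            if t.cds is not None:
                for a, b in t.exons:
                    c0, c1 = max(a, t.cds[0]), min(b, t.cds[1])
                    if c0 < c1:
                        fh.write(
                            f"{t.contig}\tsim\tCDS\t{c0 + 1}\t{c1}\t.\t{t.strand}\t.\t{attrs}\n"
                        )


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_sam(sample: SampleSim, db: ReferenceDB, path) -> None:
    """Synthetic alignment of the sample's reads against the custom reference."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for lid in sorted(db.loci):
            fh.write(f"@SQ\tSN:{lid}\tLN:{len(db.loci[lid].context_seq)}\n")
        for jid in sorted(db.junctions):
            fh.write(f"@SQ\tSN:{jid}\tLN:{len(db.junctions[jid].seq)}\n")
        for line in sample.sam_lines:
            fh.write(line + "\n")


def write_panel(panel: list[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\n")
        for lid in panel:
            fh.write(lid + "\n")


def write_cohort(cohort: CohortSim, outdir) -> dict[str, Path]:
    """Write every cohort artifact under ``outdir``; returns the path map."""
    from .refdb import write_reference

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    ref = cohort.ref
    paths["genome"] = outdir / "genome.fa"
    write_fasta(ref.genome, paths["genome"])
    paths["annotation"] = outdir / "annotation.gtf"
    write_gtf(ref.transcripts, paths["annotation"])
    paths["reference_fasta"] = outdir / "reference.fa"
    paths["catalog"] = outdir / "catalog.tsv"
    if ref.db.loci or ref.db.junctions:
        write_reference(ref.db, paths["reference_fasta"], paths["catalog"])
    paths["panel"] = outdir / "panel.tsv"
    write_panel(ref.panel, paths["panel"])
    paths["truth"] = outdir / "truth_loci.tsv"
    ref.truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["mmr_cds"] = outdir / "mmr_cds.fa"
    write_fasta(ref.mmr_cds, paths["mmr_cds"])
    for s in cohort.samples:
        paths[f"fastq:{s.sample_id}"] = outdir / f"{s.sample_id}.fastq"
        write_fastq(s.reads, paths[f"fastq:{s.sample_id}"])
        paths[f"sam:{s.sample_id}"] = outdir / f"{s.sample_id}.sam"
        write_sam(s, ref.db, paths[f"sam:{s.sample_id}"])
        paths[f"mmr:{s.sample_id}"] = outdir / f"{s.sample_id}.mmr.fastq"
        write_fastq(s.mmr_reads, paths[f"mmr:{s.sample_id}"])
    labels = pd.DataFrame(
        [(s.sample_id, s.label) for s in cohort.samples],
        columns=["sample_id", "label"],
    )
    paths["labels"] = outdir / "labels.tsv"
    labels.to_csv(paths["labels"], sep="\t", index=False)
    return paths
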