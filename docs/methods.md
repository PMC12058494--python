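# Methods

## Model and procedure

`msirna` treats MSI detection as a per-locus length-genotyping problem on
RNA-seq reads. Replication slippage at a mononucleotide run changes its
length; in mismatch-repair-deficient cells these changes escape correction
and accumulate, so the read-length distribution over an unstable locus
develops secondary modes at non-reference lengths. The pipeline has four
stages.

**Reference construction.** Annotated transcripts (GTF/GFF3 exon + CDS
features; UTRs derived from CDS vs exon extents) are scanned for maximal
homopolymer runs of ≥ 5 bases. Each run × region class (coding, 5′UTR,
3′UTR, intron) becomes one locus with a 60-nt sequence context centred on
the run, extracted in transcript orientation; isoforms sharing a run and
region merge into one locus. When an intronic run lies within 50 bp of a
splice site of an exon, two 30+30-nt junction references are emitted: the
expected junction joining the exon to its upstream neighbour, and (for
internal exons) the skip junction joining the two neighbours directly.
Aligning or matching reads against this compact reference, instead of the
genome, keeps counting cheap and storage small.

**Read ingest.** A read contributes to a locus histogram only if it
contains the entire run plus at least one matching non-repeat anchor base
on each side, and the observed run is a pure homopolymer (interrupted runs
are rejected rather than repaired — conservative under sequencing error).
A junction-spanning read must cover one full 30-nt side and ≥ 8 nt of the
other, contiguously. Two intake paths share these contracts: SAM
alignments against the emitted reference (mapq ≥ 30, primary alignments
only), and a built-in matcher that assigns raw reads by exact 16-mer seeds
anchored in non-repeat context regions (seeds may cross the flank/run
boundary so that long runs remain matchable), verifies candidates with the
shared rules (allowing ≤ 2 flank mismatches), and drops reads verifying
against more than one entry as ambiguous — mirroring the intent of the
mapq filter. On clean reads the two paths are exactly equivalent (tested).

**Scoring.** See the README for the S(m) formula. Design choices worth
recording: the numerator weight is |i|, the offset magnitude — the
skip-score reduction at a fixed weight of 5 only makes sense under that
reading; length classes failing the 10% filter are excluded from both
sums; the skip-score denominator is total junction coverage (expected +
skip reads), the closest analogue of N at a junction. Statuses form a
three-way partition (MSI-H / borderline / MSS) with only MSI-H counting
toward the sample-level pH — conservative, and configurable. All printed
inequalities are implemented exactly as stated: S ≥ 0.75, r_i/N ≥ 10%,
coverage ≥ 15, ≥ 5 mutant reads, expressed fraction strictly > 30%, pH
strictly > 35%. "Expressed" is coverage ≥ 15 alone; requiring mutant reads
for expression would empty the pH denominator in stable samples, so the
≥ 5-mutant-read condition gates instability eligibility instead.

**MMRd estimation.** Reads are counted against spliced CDS sequences of
MLH1, MSH2 and MSH6 (PMS2 excluded by default: its expression stays high
even in MSI-H samples and its dysregulation is rare; the gene set follows
the supplied CDS FASTA). Counts are divided by CDS length and expressed as
percentages of the normalized total; MMRd iff MLH1 or MSH2 < 15% or
MSH6 < 10% (strict `<`), with a 35% ± 10% normal-band annotation. A floor
of 100 assigned reads guards against calls from noise (the source method
states no floor; this is our choice).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_len` | 5 nt | minimum homopolymer length catalogued |
| context length | 60 nt | sequence context per locus (truncated + flagged at contig ends) |
| splice window | 50 bp | max intronic-run distance from a splice site for junction extraction |
| `mapq_min` | 30 | SAM mapping-quality floor |
| `class_min_frac` | 0.10 | minimum r_i/N for a mutant length class |
| `score_msih_cutoff` / `score_low_cutoff` | 0.75 / 0.20 | per-locus status cutoffs |
| `expressed_min_cov` | 15 | reads for a locus to count as expressed |
| `mutated_min_reads` | 5 | mutant reads for instability eligibility |
| `panel_expressed_min_frac` | 0.30 | expressed panel fraction gate (strict >) |
| `ph_msih_frac` | 0.35 | sample MSI-H threshold on pH (strict >) |
| `skip_weight` | 5 | fixed offset weight for exon-skip scoring |
| `seed_len` / `max_mismatch` | 16 / 2 | built-in matcher seeds and flank tolerance |

Cohort-stage defaults: recurrent events require instability in ≥ 25% of
MSI samples and ≤ 0 MSS samples; panel design keeps 3′/5′UTR loci of
15–25 bp, unstable in ≥ 50% of labelled MSI samples, leaking into no MSS
sample, expressed in ≥ 50% of samples. The source method states no values
for these; all are configurable.

## The synthetic world

The simulator's defaults are the conditions under which end-to-end label
recovery is asserted: a 100-locus 3′UTR panel (run lengths 15–25 nt, the
slippage-prone range), 50× mean per-locus coverage (Poisson), 10 MSI and
10 MSS samples. In MSI samples, 60% of panel loci are unstable: a fraction
0.4 of their reads carries that locus's planted offset — deletion with
probability 0.9, magnitude geometric (p = 0.5) truncated at 3, matching
the deletion-dominated slippage seen at runs like T17. All mutant reads at
a locus share one offset (a dominant mutant allele), the regime the score
is designed for; spreading the same mutant mass over three length classes
can dilute each below the 10% filter or the 0.75 cutoff, which is a
property of the statistic, not of the generator. MSS samples carry a 2%
slippage-like background. One gene reproduces the known exon-skipping
geometry (intronic T17 ending 2 nt before an internal exon's acceptor
site), with 30% of junction reads supporting the skip in MSI samples.
MMR reads are multinomial over CDS length × expression, with MLH1 at 15%
relative expression in MSI samples. Reads are 50 nt — inside the 50–150 nt
range of real cohorts, and short enough that a read with a deletion always
fits within the 60-nt reference context for SAM emission — and drawn
uniformly over positions containing the full run plus both anchors, so
every read is genotypable at zero error rate.

What the simulator does not emulate: transcriptome-wide expression
variation and polyA-selection bias, spliced alignment artefacts, PCR
duplicates, indel sequencing errors inside flanks, and real inter-locus
sequence homology. A green end-to-end test therefore establishes that the
scoring machinery separates the planted regimes, not that real-cohort
concordance figures are reproduced.

## Numerical and degenerate-input choices

Scores are kept in full double precision; no rounding before threshold
comparisons. N = 0 gives status `not_expressed`; an empty M₁ gives
`no_mutant` (no score). A skip event with zero skip reads or zero junction
coverage is undefined and never reported. Runs containing N or interrupted
runs are excluded from the catalog; contexts truncated at contig ends are
kept and flagged. Region of a run crossing a boundary is that of its first
base in transcript orientation. Locus ids are
`gene|contig|start|base|length|region` (1-based start) — deterministic and
merge-stable; the region field disambiguates runs annotated in two region
classes by different isoforms. Transcripts without a CDS are skipped: the
region vocabulary is undefined for them. Junction extraction anchors on
the *skipped* exon's splice sites (consistent with the known T17 driver
geometry); exon pairs with UTR-resident microsatellites near splice sites
are not extracted — only intronic-side proximity counts. Reads assignable
to multiple loci, and duplicate read names in SAM, are handled as
described in the ingest section (drop; process independently).

## Known limitations

* The built-in matcher is exact-seed based: reads whose every informative
  16-mer is hit by a sequencing error go unassigned (at realistic error
  rates this is a small, unbiased loss).
* MSI calls need adequate depth: with low coverage few panel loci pass the
  expression gate and the call degrades to `undetermined` by design.
* The MMRd check covers expression loss only — not missense variants,
  structural variants, or promoter methylation itself.
* Very long runs (L ≥ 50) leave little flank inside the 60-nt context;
  such loci are catalogued but hard to genotype with short reads.
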