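"""Per-locus instability scores and the sample-level MSI call.

The instability score of a microsatellite m with length histogram
{r_i} (i = observed run length − L(m), i=0 the reference class) is

    S(m) = log10( sum_{i in M1} |i| * r_i^2  /  sum_{i in M0} r_i )

where M1 keeps the non-reference length classes carrying at least 10% of
the locus coverage N, and M0 = M1 ∪ {0}.  The quadratic numerator rewards
abundant, long length shifts; the |i| weight makes a 2-nt slippage count
double a 1-nt one.  A locus is MSI-H when S >= 0.75; scores in [0.2, 0.75)
are reported as borderline and below 0.2 as MSS.

An exon-skipping event with r_s skip-supporting reads over a junction with
total spanning coverage D is scored with the same functional form at a
fixed offset weight of 5 (skipped transcripts are partly removed by
nonsense-mediated decay, so the supporting read count understates the
event):

    Sk = log10( 5 * r_s^2 / D )

A sample is called MSI-H when, among the expressed panel loci (coverage
>= 15), the fraction pH called MSI-H (with >= 5 mutant reads) exceeds 35%;
the call is made only when more than 30% of the panel is expressed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, fields
from typing import Iterable, Mapping

from .ingest import JunctionCounts, LengthHistogram

STATUS_MSIH = "MSI-H"
STATUS_BORDERLINE = "borderline"
STATUS_MSS = "MSS"
STATUS_NOT_EXPRESSED = "not_expressed"
STATUS_NO_MUTANT = "no_mutant"
CALL_UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class ScoreParams:
    """All scoring thresholds, at their published defaults."""

    class_min_frac: float = 0.10
    score_msih_cutoff: float = 0.75
    score_low_cutoff: float = 0.20
    expressed_min_cov: int = 15
    mutated_min_reads: int = 5
    panel_expressed_min_frac: float = 0.30
    ph_msih_frac: float = 0.35
    skip_weight: float = 5.0

    def __post_init__(self) -> None:
        for name in ("class_min_frac", "panel_expressed_min_frac", "ph_msih_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.score_low_cutoff >= self.score_msih_cutoff:
            raise ValueError("score_low_cutoff must be < score_msih_cutoff")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "ScoreParams":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise KeyError(f"unknown scoring parameters: {sorted(unknown)}")
        return cls(**mapping)


@dataclass
class LocusScore:
    locus_id: str
    S: float | None
    status: str
    N: int
    mutant_reads: int
    M1_classes: tuple[int, ...] = ()


@dataclass
class SkipScore:
    pair_id: str
    linked_locus_id: str
    Sk: float | None
    reported: bool
    r_expected: int
    r_skip: int


@dataclass
class SampleCall:
    sample_id: str
    panel_size: int
    n_expressed: int
    n_msih: int
    expressed_frac: float
    pH: float | None
    call: str


def locus_score(hist: LengthHistogram, p: ScoreParams = ScoreParams()) -> LocusScore:
    """Score one locus from its length histogram (see module docstring)."""
    n = hist.N
    if n == 0:
        return LocusScore(hist.locus_id, None, STATUS_NOT_EXPRESSED, 0, 0)
    m1 = tuple(
        sorted(
            i
            for i, r in hist.counts.items()
            if i != 0 and r > 0 and r / n >= p.class_min_frac
        )
    )
    mut = hist.mutant_reads
    if not m1:
        return LocusScore(hist.locus_id, None, STATUS_NO_MUTANT, n, mut)
    num = sum(abs(i) * hist.counts[i] ** 2 for i in m1)
    den = sum(hist.counts[i] for i in m1) + hist.counts.get(0, 0)
    s = math.log10(num / den)
    if s >= p.score_msih_cutoff:
        status = STATUS_MSIH
    elif s >= p.score_low_cutoff:
        status = STATUS_BORDERLINE
    else:
        status = STATUS_MSS
    return LocusScore(hist.locus_id, s, status, n, mut, m1)


def skip_score(jc: JunctionCounts, p: ScoreParams = ScoreParams()) -> SkipScore:
    """Score one exon-skipping event from its junction read counts."""
    d = jc.total
    if jc.r_skip == 0 or d == 0:
        return SkipScore(jc.pair_id, jc.linked_locus_id, None, False, jc.r_expected, jc.r_skip)
    sk = math.log10(p.skip_weight * jc.r_skip**2 / d)
    return SkipScore(
        jc.pair_id,
        jc.linked_locus_id,
        sk,
        sk >= p.score_msih_cutoff,
        jc.r_expected,
        jc.r_skip,
    )


def event_eligible(hist: LengthHistogram, p: ScoreParams = ScoreParams()) -> bool:
    """Coverage >= 15 and at least five reads carrying a mutated repeat."""
    return hist.N >= p.expressed_min_cov and hist.mutant_reads >= p.mutated_min_reads


def sample_call(
    sample_id: str,
    panel: Iterable[str],
    histograms: Mapping[str, LengthHistogram],
    p: ScoreParams = ScoreParams(),
) -> SampleCall:
    """Aggregate panel locus scores into the sample-level MSI call.

    The call is attempted only when the expressed fraction of the panel
    exceeds ``panel_expressed_min_frac`` (strictly); a locus counts toward
    pH when it is expressed, carries >= 5 mutant reads and scores MSI-H.
    """
    panel = list(panel)
    if not panel:
        raise ValueError("empty panel")
    n_expressed = 0
    n_msih = 0
    for lid in panel:
        h = histograms.get(lid)
        if h is None or h.N < p.expressed_min_cov:
            continue
        n_expressed += 1
        sc = locus_score(h, p)
        if sc.status == STATUS_MSIH and event_eligible(h, p):
            n_msih += 1
    expressed_frac = n_expressed / len(panel)
    if expressed_frac <= p.panel_expressed_min_frac:
        return SampleCall(
            sample_id, len(panel), n_expressed, n_msih, expressed_frac, None, CALL_UNDETERMINED
        )
    ph = n_msih / n_expressed
    call = STATUS_MSIH if ph > p.ph_msih_frac else STATUS_MSS
    return SampleCall(sample_id, len(panel), n_expressed, n_msih, expressed_frac, ph, call)


def rescore(
    histograms: Mapping[str, LengthHistogram],
    p: ScoreParams = ScoreParams(),
) -> dict[str, LocusScore]:
    """Recompute every locus score from stored histograms (pure, no re-ingest)."""
    return {lid: locus_score(h, p) for lid, h in histograms.items()}


def _params_header(p: ScoreParams) -> str:
    return "".join(f"# {k}={v}\n" for k, v in sorted(asdict(p).items()))


def write_scores_tsv(scores: Mapping[str, LocusScore], p: ScoreParams, path) -> None:
    """Per-locus score table; parameters echoed as comment header lines."""
    with open(path, "w") as fh:
        fh.write(_params_header(p))
        fh.write("locus_id\tN\tmutant_reads\tS\tstatus\tM1_classes\n")
        for lid in sorted(scores):
            sc = scores[lid]
            s = "" if sc.S is None else f"{sc.S:.6f}"
            m1 = ",".join(map(str, sc.M1_classes))
            fh.write(f"{lid}\t{sc.N}\t{sc.mutant_reads}\t{s}\t{sc.status}\t{m1}\n")


def write_sample_call_tsv(call: SampleCall, p: ScoreParams, path) -> None:
    with open(path, "w") as fh:
        fh.write(_params_header(p))
        fh.write("sample_id\tpanel_size\tn_expressed\tn_msih\texpressed_frac\tpH\tcall\n")
        ph = "" if call.pH is None else f"{call.pH:.6f}"
        fh.write(
            f"{call.sample_id}\t{call.panel_size}\t{call.n_expressed}\t{call.n_msih}\t"
            f"{call.expressed_frac:.6f}\t{ph}\t{call.call}\n"
        )


def call_summary_json(call: SampleCall, p: ScoreParams) -> str:
    return json.dumps(
        {"sample": asdict(call), "params": asdict(p)}, indent=2, sort_keys=True
    )
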