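"""Shared fixtures: a hand-enumerable toy annotation and small simulated cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from msirna.refdb import TranscriptModel
from msirna.simdata import SimConfig, simulate_cohort

BASES = "ACGT"


def _background(rng: np.random.Generator, n: int) -> list[str]:
    """Random sequence with no homopolymer longer than 3 nt."""
    out: list[str] = []
    for _ in range(n):
        if len(out) >= 3 and out[-1] == out[-2] == out[-3]:
            out.append([b for b in BASES if b != out[-1]][rng.integers(3)])
        else:
            out.append(BASES[rng.integers(4)])
    return out


def _plant(seq: list[str], start: int, base: str, length: int) -> None:
    seq[start : start + length] = [base] * length
    for pos in (start - 1, start + length):
        if 0 <= pos < len(seq) and seq[pos] == base:
            seq[pos] = next(b for b in BASES if b != base)


@pytest.fixture(scope="session")
def toy_genome() -> dict[str, str]:
    """One 800-nt contig with a planted A7 (3'UTR) and T17 (intronic) run.

    Layout (0-based half-open):
      * gene G1: transcripts T1 (exon 100-340) and T2 (exon 80-340), both
        CDS 100-220; A7 run at [250, 257) in the shared 3'UTR.
      * gene G2: transcript T3, exons (500,560)/(600,640)/(700,760),
        CDS 500-760; T17 run at [581, 598), ending 2 nt before the
        acceptor site of the middle exon (position 600).
    """
    rng = np.random.default_rng(20240917)
    seq = _background(rng, 800)
    _plant(seq, 250, "A", 7)
    _plant(seq, 581, "T", 17)
    for pos in (598, 599):  # keep the acceptor gap free of T
        if seq[pos] == "T":
            seq[pos] = "C"
    return {"chrT": "".join(seq)}


@pytest.fixture(scope="session")
def toy_transcripts() -> list[TranscriptModel]:
    return [
        TranscriptModel("T1", "G1", "chrT", "+", [(100, 340)], (100, 220)),
        TranscriptModel("T2", "G1", "chrT", "+", [(80, 340)], (100, 220)),
        TranscriptModel(
            "T3", "G2", "chrT", "+", [(500, 560), (600, 640), (700, 760)], (500, 760)
        ),
    ]


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(seed=11, n_panel_loci=12, n_msi=2, n_mss=2)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return simulate_cohort(small_cfg)
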