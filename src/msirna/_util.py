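"""Small shared helpers."""

from __future__ import annotations

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (N preserved)."""
    return seq.translate(_COMP)[::-1]


def fetch(genome, contig: str, start: int, end: int) -> str:
    """Fetch genome[contig][start:end] (0-based half-open) as an upper-case string.

    ``genome`` may be a plain dict of strings or a pyfaidx.Fasta.
    """
    if isinstance(genome, dict):
        seq = genome[contig][start:end]
    else:
        seq = str(genome[contig][start:end])
    return str(seq).upper()


def contig_length(genome, contig: str) -> int:
    if isinstance(genome, dict):
        return len(genome[contig])
    return len(genome[contig])
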