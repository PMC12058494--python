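"""Cross-sample analysis: recurrent MSI-specific events, panel design, tracks.

Events (unstable microsatellites or skip junctions) from many samples are
arranged in a matrix of {unstable, stable, not_expressed} cells.  Recurrent
MSI-specific events are those unstable in a minimum fraction of MSI-called
samples and in at most a fixed number of MSS samples.  The same machinery
drives de-novo panel design (3'UTR, 15-25 bp, quasi-exclusive instability
in MSI samples) and the export of Circos-compatible text tile tracks plus a
built-in tile figure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .ingest import JunctionCounts, LengthHistogram
from .refdb import MicrosatelliteLocus
from .scoring import (
    STATUS_MSIH,
    ScoreParams,
    event_eligible,
    locus_score,
    skip_score,
)

CELL_UNSTABLE = "unstable"
CELL_STABLE = "stable"
CELL_NOT_EXPRESSED = "not_expressed"

# numeric codes used in track files and the tile plot
CELL_CODES = {CELL_NOT_EXPRESSED: 0, CELL_STABLE: 1, CELL_UNSTABLE: 2}


@dataclass
class EventMatrix:
    """Events x samples status matrix with per-event metadata and sample calls."""

    cells: pd.DataFrame  # index=event_id, columns=sample_id, values in CELL_CODES keys
    event_meta: pd.DataFrame  # index=event_id: kind, region, contig, start, end, ref_length
    sample_calls: dict[str, str] = field(default_factory=dict)


def _locus_cell(h: LengthHistogram | None, p: ScoreParams) -> str:
    if h is None or h.N < p.expressed_min_cov:
        return CELL_NOT_EXPRESSED
    if event_eligible(h, p) and locus_score(h, p).status == STATUS_MSIH:
        return CELL_UNSTABLE
    return CELL_STABLE


def _skip_cell(jc: JunctionCounts | None, p: ScoreParams) -> str:
    if jc is None or jc.total < p.expressed_min_cov:
        return CELL_NOT_EXPRESSED
    return CELL_UNSTABLE if skip_score(jc, p).reported else CELL_STABLE


def build_event_matrix(
    sample_histograms: Mapping[str, Mapping[str, LengthHistogram]],
    sample_junctions: Mapping[str, Mapping[str, JunctionCounts]],
    loci: Mapping[str, MicrosatelliteLocus],
    sample_calls: Mapping[str, str],
    p: ScoreParams = ScoreParams(),
) -> EventMatrix:
    """Evaluate every locus and skip junction in every sample."""
    samples = sorted(sample_histograms)
    event_ids: list[str] = sorted(loci)
    pair_ids = sorted({pid for jm in sample_junctions.values() for pid in jm})
    meta_rows = []
    data: dict[str, list[str]] = {s: [] for s in samples}
    for lid in event_ids:
        m = loci[lid]
        meta_rows.append(
            {
                "event_id": lid,
                "kind": "locus",
                "region": m.region,
                "contig": m.contig,
                "start": m.start + 1,
                "end": m.end,
                "ref_length": m.ref_length,
            }
        )
        for s in samples:
            data[s].append(_locus_cell(sample_histograms[s].get(lid), p))
    for pid in pair_ids:
        linked = next(
            (jm[pid].linked_locus_id for jm in sample_junctions.values() if pid in jm),
            "",
        )
        lm = loci.get(linked)
        meta_rows.append(
            {
                "event_id": pid,
                "kind": "skip",
                "region": "junction",
                "contig": lm.contig if lm else "",
                "start": lm.start + 1 if lm else 0,
                "end": lm.end if lm else 0,
                "ref_length": lm.ref_length if lm else 0,
            }
        )
        for s in samples:
            data[s].append(_skip_cell(sample_junctions[s].get(pid), p))
    all_ids = event_ids + pair_ids
    cells = pd.DataFrame(data, index=pd.Index(all_ids, name="event_id"))
    meta = pd.DataFrame(meta_rows).set_index("event_id")
    return EventMatrix(cells, meta, dict(sample_calls))


def select_recurrent(
    matrix: EventMatrix,
    min_msi_frac: float = 0.25,
    max_mss_count: int = 0,
) -> list[str]:
    """Events unstable in >= ``min_msi_frac`` of MSI samples and <= ``max_mss_count`` MSS samples.

    Sorted by MSI recurrence descending, ties broken by event id.
    """
    msi = [s for s in matrix.cells.columns if matrix.sample_calls.get(s) == "MSI-H"]
    mss = [s for s in matrix.cells.columns if matrix.sample_calls.get(s) == "MSS"]
    if not msi:
        return []
    out: list[tuple[float, str]] = []
    for eid, row in matrix.cells.iterrows():
        n_msi = sum(row[s] == CELL_UNSTABLE for s in msi)
        n_mss = sum(row[s] == CELL_UNSTABLE for s in mss)
        frac = n_msi / len(msi)
        if frac >= min_msi_frac and n_mss <= max_mss_count:
            out.append((frac, eid))
    out.sort(key=lambda t: (-t[0], t[1]))
    return [eid for _, eid in out]


def design_panel(
    matrix: EventMatrix,
    labels: Mapping[str, str],
    length_min: int = 15,
    length_max: int = 25,
    regions: Iterable[str] = ("utr3", "utr5"),
    min_msi_unstable_frac: float = 0.5,
    max_mss_unstable: int = 0,
    min_expressed_frac: float = 0.5,
) -> pd.DataFrame:
    """Candidate panel loci: region + length filters and MSI-exclusive instability.

    ``labels`` gives the known per-sample status (MSI-H/MSS) used as truth;
    loci must be expressed in >= ``min_expressed_frac`` of all samples,
    unstable in >= ``min_msi_unstable_frac`` of MSI samples and in at most
    ``max_mss_unstable`` MSS/normal samples.
    """
    regions = set(regions)
    msi = [s for s in matrix.cells.columns if labels.get(s) == "MSI-H"]
    mss = [s for s in matrix.cells.columns if labels.get(s) == "MSS"]
    rows = []
    for eid, meta in matrix.event_meta.iterrows():
        if meta["kind"] != "locus" or meta["region"] not in regions:
            continue
        if not length_min <= meta["ref_length"] <= length_max:
            continue
        row = matrix.cells.loc[eid]
        n_samples = len(row)
        expressed = sum(v != CELL_NOT_EXPRESSED for v in row)
        n_msi_unst = sum(row[s] == CELL_UNSTABLE for s in msi)
        n_mss_unst = sum(row[s] == CELL_UNSTABLE for s in mss)
        if expressed / n_samples < min_expressed_frac:
            continue
        if not msi or n_msi_unst / len(msi) < min_msi_unstable_frac:
            continue
        if n_mss_unst > max_mss_unstable:
            continue
        rows.append(
            {
                "locus_id": eid,
                "region": meta["region"],
                "ref_length": meta["ref_length"],
                "msi_unstable_frac": n_msi_unst / len(msi),
                "mss_unstable_count": n_mss_unst,
                "expressed_frac": expressed / n_samples,
            }
        )
    cols = [
        "locus_id",
        "region",
        "ref_length",
        "msi_unstable_frac",
        "mss_unstable_count",
        "expressed_frac",
    ]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(
        ["msi_unstable_frac", "locus_id"], ascending=[False, True]
    ).reset_index(drop=True)


def write_panel_tsv(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, sep="\t", index=False)


def read_panel_tsv(path) -> list[str]:
    df = pd.read_csv(path, sep="\t")
    return list(df["locus_id"])


def export_tracks(
    matrix: EventMatrix,
    events: Iterable[str],
    outdir,
    figure: str | None = "tiles.png",
) -> list[Path]:
    """Write per-sample Circos text tile tracks and a tile figure.

    Track lines are ``contig start end value`` with value the cell code
    (0 = not expressed, 1 = stable, 2 = unstable); byte-stable for
    identical inputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    events = [e for e in events if e in matrix.cells.index]
    written: list[Path] = []
    for sample in matrix.cells.columns:
        path = outdir / f"{sample}.track.txt"
        with open(path, "w") as fh:
            for eid in events:
                meta = matrix.event_meta.loc[eid]
                code = CELL_CODES[matrix.cells.loc[eid, sample]]
                fh.write(f"{meta['contig']} {meta['start']} {meta['end']} {code}\n")
        written.append(path)
    if figure and events:
        written.append(_tile_figure(matrix, events, outdir / figure))
    return written


def _tile_figure(matrix: EventMatrix, events: list[str], path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    sub = matrix.cells.loc[events]
    codes = sub.apply(lambda col: [CELL_CODES[v] for v in col])
    fig_w = max(4.0, 0.4 * len(sub.columns) + 2)
    fig_h = max(3.0, 0.25 * len(events) + 1.5)
    fig, ax = plt.subplots(figsize=(fig_w, fig_h))
    cmap = ListedColormap(["#d9d9d9", "#4575b4", "#d73027"])
    ax.imshow(codes.values, aspect="auto", cmap=cmap, vmin=0, vmax=2)
    ax.set_xticks(range(len(sub.columns)))
    ax.set_xticklabels(sub.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(events)))
    ax.set_yticklabels(events, fontsize=5)
    ax.set_xlabel("sample")
    ax.set_ylabel("event")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def write_event_matrix_tsv(matrix: EventMatrix, path) -> None:
    df = matrix.event_meta.join(matrix.cells)
    df.to_csv(path, sep="\t")
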