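"""Tab-separated readers/writers for events, windows and removal logs.

Event tables round-trip: ``read_event_table(write_event_table(events))``
reproduces the events.  Internal coordinates are 1-based inclusive; BED
exports are 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .events import SpliceEvent
from .mask import RemovalRecord
from .windows import SpliceWindow

EVENT_COLUMNS = ["event_id", "type", "gene_id", "chrom", "strand", "introns",
                 "exon", "inclusion_transcripts", "exclusion_transcripts",
                 "boundary_mode", "first_intron", "u12"]


def write_event_table(events: list[SpliceEvent], path: str | Path,
                      header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(EVENT_COLUMNS) + "\n")
        for ev in events:
            fh.write("\t".join([
                ev.event_id, ev.type, ev.gene_id, ev.chrom, ev.strand,
                ",".join(f"{s}-{e}" for s, e in ev.introns),
                f"{ev.exon[0]}-{ev.exon[1]}" if ev.exon else ".",
                ";".join(sorted(ev.inclusion_transcripts)),
                ";".join(sorted(ev.exclusion_transcripts)),
                ev.boundary_mode,
                str(ev.first_intron), str(ev.u12),
            ]) + "\n")


def read_event_table(path: str | Path) -> list[SpliceEvent]:
    tab = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(EVENT_COLUMNS) - set(tab.columns)
    if missing:
        raise ValueError(f"event table {path} lacks columns {sorted(missing)}")
    events = []
    for row in tab.itertuples(index=False):
        introns = tuple(tuple(int(x) for x in part.split("-"))
                        for part in row.introns.split(","))
        exon = None if row.exon == "." else tuple(int(x) for x in row.exon.split("-"))
        events.append(SpliceEvent(
            event_id=row.event_id, gene_id=row.gene_id, type=row.type,
            chrom=row.chrom, strand=row.strand, introns=introns, exon=exon,
            inclusion_transcripts=frozenset(row.inclusion_transcripts.split(";")),
            exclusion_transcripts=frozenset(row.exclusion_transcripts.split(";")),
            boundary_mode=row.boundary_mode,
            first_intron=row.first_intron == "True",
            u12=row.u12 == "True",
        ))
    return events


def write_event_bed(events: list[SpliceEvent], path: str | Path) -> None:
    """BED6 of event core intervals (0-based half-open)."""
    with open(path, "w") as fh:
        for ev in events:
            lo = min(s for s, _ in ev.introns)
            hi = max(e for _, e in ev.introns)
            if ev.exon:
                lo, hi = min(lo, ev.exon[0]), max(hi, ev.exon[1])
            fh.write(f"{ev.chrom}\t{lo - 1}\t{hi}\t{ev.event_id}\t0\t{ev.strand}\n")


def write_windows_bed(windows: list[SpliceWindow], path: str | Path,
                      names: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, w in enumerate(windows):
            name = names[i] if names else w.side
            fh.write(f"{w.chrom}\t{w.start - 1}\t{w.end}\t{name}\t0\t{w.strand}\n")


def write_removal_log(records: list[RemovalRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("event_id\tchrom\tpos\tref\talt\tkind\tems_transition\t"
                 "window_start\twindow_end\tside\n")
        for r in records:
            v = r.variant
            fh.write("\t".join([
                r.event_id, v.chrom, str(v.pos), v.ref, v.alt, v.kind,
                str(v.is_ems_transition), str(r.window.start),
                str(r.window.end), r.side,
            ]) + "\n")
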