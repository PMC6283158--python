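"""Splice-site windows used for variant masking and site-strength scoring.

The 5' (donor) window covers the last 3 exonic and the first 10 intronic
bases (13 nt); the 3' (acceptor) window the last 14 intronic and the first
3 exonic bases (17 nt), both in transcript orientation.  On the minus
strand the windows are mirrored so the exonic/intronic base counts are
preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .annotation import Intron
from .events import SpliceEvent

FIVE_PRIME_EXONIC = 3
FIVE_PRIME_INTRONIC = 10
THREE_PRIME_INTRONIC = 14
THREE_PRIME_EXONIC = 3
FIVE_PRIME_WIDTH = FIVE_PRIME_EXONIC + FIVE_PRIME_INTRONIC  # 13
THREE_PRIME_WIDTH = THREE_PRIME_INTRONIC + THREE_PRIME_EXONIC  # 17


@dataclass(frozen=True)
class SpliceWindow:
    """A genomic interval (1-based inclusive) around one splice site."""

    chrom: str
    start: int
    end: int
    side: str  # "five_prime" | "three_prime"
    strand: str
    intron: tuple[int, int] | None = None

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, start: int, end: int) -> bool:
        return start <= self.end and end >= self.start


def five_prime_window(chrom: str, strand: str, intron_start: int | None = None,
                      intron_end: int | None = None) -> SpliceWindow:
    """Donor-site window.  Needs the intron start on '+', the end on '-'."""
    if strand == "+":
        if intron_start is None:
            raise ValueError("intron_start required for 5' window on + strand")
        start, end = intron_start - FIVE_PRIME_EXONIC, intron_start + FIVE_PRIME_INTRONIC - 1
    else:
        if intron_end is None:
            raise ValueError("intron_end required for 5' window on - strand")
        start, end = intron_end - FIVE_PRIME_INTRONIC + 1, intron_end + FIVE_PRIME_EXONIC
    start = _clip(start, chrom)
    return SpliceWindow(chrom, start, end, "five_prime", strand,
                        intron=(intron_start, intron_end) if intron_start and intron_end else None)


def three_prime_window(chrom: str, strand: str, intron_start: int | None = None,
                       intron_end: int | None = None) -> SpliceWindow:
    """Acceptor-site window.  Needs the intron end on '+', the start on '-'."""
    if strand == "+":
        if intron_end is None:
            raise ValueError("intron_end required for 3' window on + strand")
        start, end = intron_end - THREE_PRIME_INTRONIC + 1, intron_end + THREE_PRIME_EXONIC
    else:
        if intron_start is None:
            raise ValueError("intron_start required for 3' window on - strand")
        start, end = intron_start - THREE_PRIME_EXONIC, intron_start + THREE_PRIME_INTRONIC - 1
    start = _clip(start, chrom)
    return SpliceWindow(chrom, start, end, "three_prime", strand,
                        intron=(intron_start, intron_end) if intron_start and intron_end else None)


def _clip(start: int, chrom: str) -> int:
    if start < 1:
        warnings.warn(
            f"splice window on {chrom} clipped at the contig start; flanking "
            "exonic bases missing",
            stacklevel=3,
        )
        return 1
    return start


def splice_windows(intron: Intron | tuple) -> tuple[SpliceWindow, SpliceWindow]:
    """Both windows of one intron, as ``(five_prime, three_prime)``."""
    if isinstance(intron, Intron):
        chrom, strand, s, e = intron.chrom, intron.strand, intron.start, intron.end
    else:
        chrom, strand, s, e = intron
    if e < s:
        raise ValueError(f"intron [{s},{e}] has end < start")
    return (
        five_prime_window(chrom, strand, intron_start=s, intron_end=e),
        three_prime_window(chrom, strand, intron_start=s, intron_end=e),
    )


def event_windows(event: SpliceEvent) -> list[SpliceWindow]:
    """All splice-site windows that define an event.

    IR/EX: the two sites of the retained/excised intron.  A5/A3: the sites
    of both competing introns.  ES: the sites of the skipping junction plus
    the two exon-flanking sites of the skipped exon (donor/acceptor of the
    flanking introns of inclusion isoforms); in the common geometry two of
    these coincide with the junction's own sites, giving three distinct
    junction-forming sites.
    """
    out: list[SpliceWindow] = []
    for s, e in event.introns:
        out.extend(splice_windows((event.chrom, event.strand, s, e)))
    if event.type == "ES" and event.exon is not None:
        es, ee = event.exon
        if event.strand == "+":
            out.append(three_prime_window(event.chrom, "+", intron_end=es - 1))
            out.append(five_prime_window(event.chrom, "+", intron_start=ee + 1))
        else:
            out.append(five_prime_window(event.chrom, "-", intron_end=es - 1))
            out.append(three_prime_window(event.chrom, "-", intron_start=ee + 1))
    # deduplicate identical windows (ES junction sites often coincide with flanks)
    seen: dict[tuple, SpliceWindow] = {}
    for w in out:
        seen.setdefault((w.chrom, w.start, w.end, w.side), w)
    return list(seen.values())
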