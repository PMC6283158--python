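"""Removal of splicing events whose splice sites overlap sequence variants.

Forward-genetic screens on mutagenised material carry residual background
mutations; any event with a SNP or indel footprint intersecting one of its
splice-site windows is removed so that apparent splicing changes caused by
mutated splice sites do not contaminate the differential results.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from pathlib import Path

import pysam

from .events import SpliceEvent
from .windows import SpliceWindow, event_windows


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int  # 1-based, left-anchored (VCF POS)
    ref: str
    alt: str

    @property
    def kind(self) -> str:
        return "SNP" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @property
    def footprint(self) -> tuple[int, int]:
        """Genomic bases occupied by the reference allele (left-anchored)."""
        return self.pos, self.pos + len(self.ref) - 1

    @property
    def is_ems_transition(self) -> bool:
        """EMS mutagenesis yields almost exclusively G->A / C->T transitions."""
        return self.kind == "SNP" and (self.ref, self.alt) in {("G", "A"), ("C", "T")}


@dataclass(frozen=True)
class RemovalRecord:
    event_id: str
    variant: Variant
    window: SpliceWindow
    side: str


def read_variants(vcf_path: str | Path, pass_only: bool = False) -> list[Variant]:
    """Read CHROM/POS/REF/ALT from a VCF; multi-allelic rows are expanded.

    With ``pass_only`` rows whose FILTER is set and not PASS are skipped.
    """
    out: list[Variant] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            if pass_only and rec.filter.keys() not in ([], ["PASS"]):
                continue
            for alt in rec.alts or ():
                out.append(Variant(rec.chrom, rec.pos, rec.ref, alt))
    return out


def filter_events(
    events: list[SpliceEvent], variants: list[Variant]
) -> tuple[list[SpliceEvent], list[RemovalRecord]]:
    """Partition events into kept and removed by splice-window overlap.

    An event is removed iff at least one variant footprint intersects at
    least one of its splice-site windows (both sites of every defining
    intron; for ES also the skipped exon's flanking sites).  Every overlap
    is reported as a :class:`RemovalRecord`; the kept and removed sets are
    disjoint and together cover the input.

    Raises ``ValueError`` when the two inputs share no chromosome names,
    which almost always indicates mismatched assemblies.
    """
    if events and variants:
        ev_chroms = {e.chrom for e in events}
        var_chroms = {v.chrom for v in variants}
        if not (ev_chroms & var_chroms):
            raise ValueError(
                "no chromosome names in common between events and variants; "
                f"events: {sorted(ev_chroms)}, variants: {sorted(var_chroms)}"
            )

    by_chrom: dict[str, list[tuple[int, int, Variant]]] = {}
    for v in variants:
        s, e = v.footprint
        by_chrom.setdefault(v.chrom, []).append((s, e, v))
    max_ref = {c: max(e - s for s, e, _ in rows) for c, rows in by_chrom.items()}
    for rows in by_chrom.values():
        rows.sort()

    kept: list[SpliceEvent] = []
    removed: list[RemovalRecord] = []
    removed_ids: set[str] = set()
    for ev in events:
        rows = by_chrom.get(ev.chrom, [])
        hits = []
        for w in event_windows(ev):
            # footprints start at most max_ref bases left of the window
            lo = bisect_left(rows, (w.start - max_ref.get(ev.chrom, 0), -1))
            for s, e, v in rows[lo:]:
                if s > w.end:
                    break
                if e >= w.start:
                    hits.append(RemovalRecord(ev.event_id, v, w, w.side))
        if hits:
            removed.extend(hits)
            removed_ids.add(ev.event_id)
        else:
            kept.append(ev)
    assert len(kept) + len(removed_ids) == len(events)
    return kept, removed
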