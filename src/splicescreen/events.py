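"""Enumeration of alternative-splicing events from transcript models.

Five event types are recognised, mirroring the standard event-level view
of a multi-isoform annotation:

IR  (intron retention)    — an intron spliced by at least one isoform and
                            fully contained within a single exon of another
                            isoform of the same gene (inclusion = retainers).
ES  (exon skipping)       — an internal exon present in one isoform while
                            another isoform bridges it with a single
                            junction spanning the exon (inclusion = exon-
                            containing isoforms).
A5 / A3                   — two introns of the same gene sharing exactly one
                            boundary: same acceptor with different donors is
                            alternative 5' (donor) choice, same donor with
                            different acceptors alternative 3' (acceptor)
                            choice, in transcript orientation (strand-aware).
                            Inclusion = isoforms carrying the shorter intron.
EX  (exitron)             — an intron whose span lies strictly inside a
                            coding (CDS) interval of the gene's reference
                            isoform; inclusion = isoforms retaining the
                            region unspliced.

IR/ES/EX events use variable boundaries (keyed by their core coordinates,
flanking exon edges free to differ); A5/A3 are strict (keyed by both full
introns, shared boundary base-identical).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .annotation import Intron, TranscriptModel

EVENT_TYPES = ("IR", "ES", "A5", "A3", "EX")

# boundary semantics per type: core-keyed ("variable") vs full-intron keyed
BOUNDARY_MODE = {"IR": "variable", "ES": "variable", "EX": "variable",
                 "A5": "strict", "A3": "strict"}


@dataclass(frozen=True)
class SpliceEvent:
    """A single alternative-splicing event with its isoform support sets.

    ``introns`` holds the defining intron interval(s): one for IR/EX (the
    retained/excised intron), one for ES (the skipping junction), two for
    A5/A3 (the competing introns, sorted by coordinates).  ``exon`` is the
    skipped-exon span for ES events, ``None`` otherwise.
    """

    event_id: str
    gene_id: str
    type: str
    chrom: str
    strand: str
    introns: tuple[tuple[int, int], ...]
    exon: tuple[int, int] | None
    inclusion_transcripts: frozenset[str]
    exclusion_transcripts: frozenset[str]
    boundary_mode: str
    first_intron: bool = False
    u12: bool = False

    def __post_init__(self) -> None:
        if self.inclusion_transcripts & self.exclusion_transcripts:
            raise ValueError(f"{self.event_id}: inclusion and exclusion sets overlap")
        if not self.inclusion_transcripts or not self.exclusion_transcripts:
            raise ValueError(f"{self.event_id}: empty inclusion or exclusion set")

    @property
    def transcripts(self) -> frozenset[str]:
        return self.inclusion_transcripts | self.exclusion_transcripts


def make_event_id(gene_id: str, etype: str, chrom: str, strand: str,
                  introns: Sequence[tuple[int, int]],
                  exon: tuple[int, int] | None = None) -> str:
    parts = [f"{s}-{e}" for s, e in sorted(introns)]
    if exon is not None:
        parts.insert(0, f"e{exon[0]}-{exon[1]}")
    return f"{gene_id};{etype};{chrom}:{':'.join(parts)}:{strand}"


def _covering_exon(t: TranscriptModel, start: int, end: int) -> bool:
    """True if some exon of ``t`` contains [start-1, end+1] (retention)."""
    return any(es <= start - 1 and end + 1 <= ee for es, ee in t.exons)


def _is_first_in_a_splicer(intron: Intron, gene_tx_ids: set[str]) -> bool:
    return any(
        intron.ordinal_by_transcript.get(tid) == 1
        for tid in intron.host_transcripts & gene_tx_ids
    )


def extract_events(
    transcripts: list[TranscriptModel],
    introns: list[Intron],
    event_type: str,
) -> list[SpliceEvent]:
    """Enumerate events of one type across all genes.

    Events are deduplicated by their deterministic ``event_id`` and the
    result is independent of the input transcript order.  Requesting EX on
    an annotation that has no CDS feature anywhere raises ``ValueError``,
    since exitron calling is defined relative to reference coding exons.
    """
    if event_type not in EVENT_TYPES:
        raise ValueError(f"unknown event type {event_type!r}; expected one of {EVENT_TYPES}")

    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)

    if event_type == "EX" and not any(t.cds for t in transcripts):
        raise ValueError(
            "exitron (EX) calling requires CDS annotation on the reference "
            "isoforms; none of the supplied transcripts carries CDS intervals"
        )

    intron_index: dict[tuple, Intron] = {i.key: i for i in introns}

    events: dict[str, SpliceEvent] = {}
    for gene_id in sorted(by_gene):
        gene_tx = by_gene[gene_id]
        if len(gene_tx) < 2 and event_type != "EX":
            continue
        gene_tx_ids = {t.transcript_id for t in gene_tx}
        # distinct introns used by this gene's transcripts
        gene_introns: dict[tuple[int, int], Intron] = {}
        for t in gene_tx:
            for s, e in t.introns:
                key = (t.chrom, t.strand, s, e)
                if key in intron_index:
                    gene_introns[(s, e)] = intron_index[key]
        chrom = gene_tx[0].chrom
        strand = gene_tx[0].strand

        if event_type == "IR":
            for (s, e), intr in gene_introns.items():
                splicers = frozenset(intr.host_transcripts & gene_tx_ids)
                retainers = frozenset(
                    t.transcript_id for t in gene_tx if _covering_exon(t, s, e)
                )
                if splicers and retainers:
                    _add_ir_like(events, "IR", gene_id, chrom, strand, (s, e),
                                 retainers, splicers, intr, gene_tx_ids)

        elif event_type == "EX":
            ref = next((t for t in gene_tx if t.is_reference), None)
            if ref is None or not ref.cds:
                continue
            for (s, e), intr in gene_introns.items():
                inside = any(cs < s and e < ce for cs, ce in ref.cds)
                if not inside:
                    continue
                splicers = frozenset(intr.host_transcripts & gene_tx_ids)
                retainers = frozenset(
                    t.transcript_id for t in gene_tx if _covering_exon(t, s, e)
                )
                if splicers and retainers:
                    _add_ir_like(events, "EX", gene_id, chrom, strand, (s, e),
                                 retainers, splicers, intr, gene_tx_ids)

        elif event_type == "ES":
            for t in gene_tx:
                for idx in range(1, len(t.exons) - 1):
                    es, ee = t.exons[idx]
                    for (js, je), intr in gene_introns.items():
                        if js <= es - 1 and ee + 1 <= je:
                            skippers = frozenset(intr.host_transcripts & gene_tx_ids)
                            containing = frozenset(
                                u.transcript_id
                                for u in gene_tx
                                if (es, ee) in u.exons[1:-1]
                            )
                            if not skippers or not containing:
                                continue
                            eid = make_event_id(gene_id, "ES", chrom, strand,
                                                [(js, je)], exon=(es, ee))
                            if eid not in events:
                                events[eid] = SpliceEvent(
                                    event_id=eid, gene_id=gene_id, type="ES",
                                    chrom=chrom, strand=strand,
                                    introns=((js, je),), exon=(es, ee),
                                    inclusion_transcripts=containing,
                                    exclusion_transcripts=skippers,
                                    boundary_mode="variable",
                                )

        else:  # A5 / A3
            keys = sorted(gene_introns)
            by_start: dict[int, list[tuple[int, int]]] = {}
            by_end: dict[int, list[tuple[int, int]]] = {}
            for s, e in keys:
                by_start.setdefault(s, []).append((s, e))
                by_end.setdefault(e, []).append((s, e))
            # same genomic start, different ends: A3 on '+', A5 on '-'
            # same genomic end, different starts: A5 on '+', A3 on '-'
            if (event_type == "A3") == (strand == "+"):
                groups = by_start.values()
            else:
                groups = by_end.values()
            for group in groups:
                if len(group) < 2:
                    continue
                for i in range(len(group)):
                    for j in range(i + 1, len(group)):
                        a, b = group[i], group[j]
                        _add_alt_ss(events, event_type, gene_id, chrom, strand,
                                    a, b, gene_introns, gene_tx_ids)

    return sorted(events.values(), key=lambda ev: ev.event_id)


def _add_ir_like(events, etype, gene_id, chrom, strand, span, retainers,
                 splicers, intr: Intron, gene_tx_ids) -> None:
    eid = make_event_id(gene_id, etype, chrom, strand, [span])
    if eid in events:
        return
    events[eid] = SpliceEvent(
        event_id=eid, gene_id=gene_id, type=etype, chrom=chrom, strand=strand,
        introns=(span,), exon=None,
        inclusion_transcripts=retainers, exclusion_transcripts=splicers,
        boundary_mode="variable",
        first_intron=_is_first_in_a_splicer(intr, gene_tx_ids),
        u12=intr.u12,
    )


def _add_alt_ss(events, etype, gene_id, chrom, strand, a, b,
                gene_introns, gene_tx_ids) -> None:
    intr_a, intr_b = gene_introns[a], gene_introns[b]
    hosts_a = frozenset(intr_a.host_transcripts & gene_tx_ids)
    hosts_b = frozenset(intr_b.host_transcripts & gene_tx_ids)
    if not hosts_a or not hosts_b:
        return
    len_a = a[1] - a[0] + 1
    len_b = b[1] - b[0] + 1
    # the shorter intron keeps more exon sequence: its hosts are inclusion
    if len_a <= len_b:
        inclusion, exclusion = hosts_a, hosts_b
    else:
        inclusion, exclusion = hosts_b, hosts_a
    eid = make_event_id(gene_id, etype, chrom, strand, [a, b])
    if eid not in events:
        events[eid] = SpliceEvent(
            event_id=eid, gene_id=gene_id, type=etype, chrom=chrom,
            strand=strand, introns=tuple(sorted([a, b])), exon=None,
            inclusion_transcripts=inclusion, exclusion_transcripts=exclusion,
            boundary_mode="strict",
        )


def extract_all_events(
    transcripts: list[TranscriptModel],
    introns: list[Intron],
    types: Iterable[str] = EVENT_TYPES,
) -> list[SpliceEvent]:
    """Run :func:`extract_events` for several types and concatenate."""
    out: list[SpliceEvent] = []
    for etype in types:
        out.extend(extract_events(transcripts, introns, etype))
    return out
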