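"""Transcript models and intron enumeration from GTF/GFF3 annotation.

Transcript structures are read from standard annotation files and turned
into light-weight records on which the event-level alternative-splicing
analyses operate.  Coordinates are 1-based inclusive throughout (GTF
convention); BED exports elsewhere convert to 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gffutils


class AnnotationError(ValueError):
    """Raised for malformed or incomplete annotation input."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript isoform: ordered exons plus optional CDS intervals.

    ``exons`` and ``cds`` are tuples of 1-based inclusive ``(start, end)``
    intervals sorted by genomic start regardless of strand.  Exactly one
    transcript per gene carries ``is_reference=True``; exitron calling is
    defined relative to that isoform's coding exons.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] | None = None
    is_reference: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"transcript {self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id} has zero exons")
        prev_end = None
        for start, end in self.exons:
            if end < start:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exon [{start},{end}] has end < start"
                )
            if prev_end is not None and start <= prev_end:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end
        if self.cds:
            for cs, ce in self.cds:
                if not any(es <= cs and ce <= ee for es, ee in self.exons):
                    raise AnnotationError(
                        f"transcript {self.transcript_id}: CDS [{cs},{ce}] not contained in any exon"
                    )

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Genomic intron intervals (gaps between consecutive exons)."""
        return tuple(
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class Intron:
    """A distinct intron interval, possibly shared by several transcripts.

    ``ordinal_by_transcript`` maps each hosting transcript to this intron's
    1-based position in transcript orientation: ordinal 1 is the 5'-most
    intron of the transcript, which on the minus strand is the intron with
    the greatest genomic coordinates.
    """

    chrom: str
    strand: str
    start: int
    end: int
    host_transcripts: set[str] = field(default_factory=set)
    ordinal_by_transcript: dict[str, int] = field(default_factory=dict)
    u12: bool = False

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.chrom, self.strand, self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _choose_reference(transcript_ids: list[str]) -> str:
    """Pick one reference isoform per gene.

    The ``.1``-suffixed model is preferred when present (annotation
    collections commonly keep the primary reference model under that
    suffix); otherwise the lexicographically smallest transcript id.
    """
    dot1 = sorted(t for t in transcript_ids if t.endswith(".1"))
    if dot1:
        return dot1[0]
    return min(transcript_ids)


def _validate_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise AnnotationError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )


def parse_annotation(gtf_path: str | Path, genome: str | Path | None = None) -> list[TranscriptModel]:
    """Parse a GTF/GFF3 file into :class:`TranscriptModel` records.

    Exon (and optional CDS) features are grouped by their transcript
    attribute; exons are normalised to ascending genomic start order.
    One reference isoform per gene is flagged.  The optional ``genome``
    argument is accepted for interface symmetry with downstream steps
    that need sequence; it is not read here.

    Returns transcripts sorted by ``(gene_id, transcript_id)``.
    """
    gtf_path = Path(gtf_path)
    _validate_lines(gtf_path)
    try:
        db = gffutils.create_db(
            str(gtf_path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # pragma: no cover - gffutils error paths vary
        raise AnnotationError(f"failed to parse {gtf_path}: {exc}") from exc

    exons: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tids = feat.attributes.get("transcript_id") or feat.attributes.get("Parent")
        gids = feat.attributes.get("gene_id")
        if not tids:
            raise AnnotationError(
                f"{gtf_path}: {feat.featuretype} feature at {feat.seqid}:{feat.start}-{feat.end} "
                "lacks a transcript_id/Parent attribute"
            )
        for tid in tids:
            rec = exons.setdefault(
                tid,
                {
                    "gene_id": gids[0] if gids else tid,
                    "chrom": feat.seqid,
                    "strand": feat.strand,
                    "exons": [],
                    "cds": [],
                },
            )
            if feat.featuretype == "exon":
                rec["exons"].append((feat.start, feat.end))
            else:
                rec["cds"].append((feat.start, feat.end))

    if not exons:
        raise AnnotationError(f"{gtf_path}: no exon features found")

    by_gene: dict[str, list[str]] = {}
    for tid, rec in exons.items():
        if not rec["exons"]:
            raise AnnotationError(f"transcript {tid} has zero exons")
        by_gene.setdefault(rec["gene_id"], []).append(tid)
    reference = {g: _choose_reference(tids) for g, tids in by_gene.items()}

    models = []
    for tid, rec in exons.items():
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=tuple(sorted(rec["exons"])),
                cds=tuple(sorted(rec["cds"])) or None,
                is_reference=(tid == reference[rec["gene_id"]]),
            )
        )
    models.sort(key=lambda t: (t.gene_id, t.transcript_id))
    return models


def mark_reference_isoforms(transcripts: list[TranscriptModel]) -> list[TranscriptModel]:
    """Return copies with ``is_reference`` set by the per-gene rule."""
    by_gene: dict[str, list[str]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t.transcript_id)
    ref = {g: _choose_reference(tids) for g, tids in by_gene.items()}
    out = []
    for t in transcripts:
        is_ref = t.transcript_id == ref[t.gene_id]
        if is_ref == t.is_reference:
            out.append(t)
        else:
            out.append(
                TranscriptModel(
                    t.transcript_id, t.gene_id, t.chrom, t.strand, t.exons, t.cds, is_ref
                )
            )
    return out


def enumerate_introns(
    transcripts: list[TranscriptModel], u12_introns: set[tuple[str, int, int]] | None = None
) -> list[Intron]:
    """Collect distinct introns across transcripts with per-transcript ordinals.

    Introns identical in ``(chrom, strand, start, end)`` are merged into a
    single record with the union of host transcripts.  Ordinals count
    introns in transcript orientation (strand-aware), starting at 1.
    ``u12_introns`` is an optional externally supplied set of
    ``(chrom, start, end)`` keys to flag minor-spliceosome introns; the
    flag is carried through, never computed.
    """
    u12_introns = u12_introns or set()
    merged: dict[tuple, Intron] = {}
    for t in transcripts:
        tx_introns = list(t.introns)
        # ordinal 1 = 5'-most in transcript orientation
        ordered = tx_introns if t.strand == "+" else list(reversed(tx_introns))
        for ordinal, (start, end) in enumerate(ordered, start=1):
            key = (t.chrom, t.strand, start, end)
            rec = merged.get(key)
            if rec is None:
                rec = Intron(
                    chrom=t.chrom,
                    strand=t.strand,
                    start=start,
                    end=end,
                    u12=(t.chrom, start, end) in u12_introns,
                )
                merged[key] = rec
            rec.host_transcripts.add(t.transcript_id)
            rec.ordinal_by_transcript[t.transcript_id] = ordinal
    return sorted(merged.values(), key=lambda i: i.key)
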