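"""Independent brute-force event oracle: literal all-isoform-pairs comparison.

Deliberately structured differently from the package implementation (plain
nested loops over ordered transcript pairs, no indexing) so it can serve
as an oracle for event-extraction equivalence tests.
"""

from __future__ import annotations


def _introns(exons):
    return [(exons[i][1] + 1, exons[i + 1][0] - 1) for i in range(len(exons) - 1)]


def _first_intron(exons, strand):
    intr = _introns(exons)
    if not intr:
        return None
    return intr[0] if strand == "+" else intr[-1]


def brute_force_events(transcripts):
    """Map (gene, type, core) -> {"inclusion": set, "exclusion": set, "first": bool}.

    Cores: IR/EX -> intron; ES -> (junction, exon); A5/A3 -> frozenset of
    the two introns.
    """
    by_gene = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)

    out = {}

    def add(gene, etype, core, incl, excl):
        key = (gene, etype, core)
        rec = out.setdefault(key, {"inclusion": set(), "exclusion": set(), "first": False})
        rec["inclusion"].update(incl)
        rec["exclusion"].update(excl)

    for gene, txs in by_gene.items():
        ref = next((t for t in txs if t.is_reference), None)
        strand = txs[0].strand
        for t1 in txs:
            for t2 in txs:
                if t1 is t2:
                    continue
                # IR: intron of t1 covered by an exon of t2
                for s, e in _introns(t1.exons):
                    for xs, xe in t2.exons:
                        if xs <= s - 1 and e + 1 <= xe:
                            add(gene, "IR", (s, e), {t2.transcript_id}, {t1.transcript_id})
                # EX: intron of t1 strictly inside a reference CDS interval,
                # retained by an exon of t2
                if ref is not None and ref.cds:
                    for s, e in _introns(t1.exons):
                        if any(cs < s and e < ce for cs, ce in ref.cds):
                            for xs, xe in t2.exons:
                                if xs <= s - 1 and e + 1 <= xe:
                                    add(gene, "EX", (s, e),
                                        {t2.transcript_id}, {t1.transcript_id})
                # ES: internal exon of t1 spanned by an intron of t2
                for xs, xe in t1.exons[1:-1]:
                    for js, je in _introns(t2.exons):
                        if js <= xs - 1 and xe + 1 <= je:
                            add(gene, "ES", ((js, je), (xs, xe)),
                                {t1.transcript_id}, {t2.transcript_id})
                # A5/A3: introns sharing exactly one boundary
                for i1 in _introns(t1.exons):
                    for i2 in _introns(t2.exons):
                        if i1 == i2:
                            continue
                        if i1[0] == i2[0] and i1[1] != i2[1]:
                            etype = "A3" if strand == "+" else "A5"
                        elif i1[1] == i2[1] and i1[0] != i2[0]:
                            etype = "A5" if strand == "+" else "A3"
                        else:
                            continue
                        len1 = i1[1] - i1[0]
                        shorter, longer = (t1, t2) if len1 < i2[1] - i2[0] else (t2, t1)
                        add(gene, etype, frozenset((i1, i2)),
                            {shorter.transcript_id}, {longer.transcript_id})

        # first-intron flag for IR/EX: retained intron is the 5'-most intron
        # of at least one transcript that splices it
        for (g, etype, core), rec in out.items():
            if g != gene or etype not in ("IR", "EX"):
                continue
            firsts = {
                t.transcript_id: _first_intron(t.exons, t.strand) for t in txs
            }
            rec["first"] = any(firsts.get(tid) == core for tid in rec["exclusion"])

    return {k: {"inclusion": frozenset(v["inclusion"]),
                "exclusion": frozenset(v["exclusion"]),
                "first": v["first"]}
            for k, v in out.items()}


def implementation_keyed(events):
    """Re-key package SpliceEvent records into the oracle's key space."""
    out = {}
    for ev in events:
        if ev.type in ("IR", "EX"):
            core = ev.introns[0]
        elif ev.type == "ES":
            core = (ev.introns[0], ev.exon)
        else:
            core = frozenset(ev.introns)
        out[(ev.gene_id, ev.type, core)] = {
            "inclusion": ev.inclusion_transcripts,
            "exclusion": ev.exclusion_transcripts,
            "first": ev.first_intron,
        }
    return out
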