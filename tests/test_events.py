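import numpy as np
import pytest

from bruteforce import brute_force_events, implementation_keyed
from conftest import random_annotation
from splicescreen.annotation import TranscriptModel, enumerate_introns, mark_reference_isoforms
from splicescreen.events import extract_all_events, extract_events


def _mk(tid, gene, strand, exons, cds=None):
    return TranscriptModel(tid, gene, "chr1", strand, exons, cds)


def _events(transcripts, etype):
    return extract_events(transcripts, enumerate_introns(transcripts), etype)


def test_ir_definitional():
    t1 = _mk("T1", "G", "+", ((1, 100), (201, 300)))
    t2 = _mk("T2", "G", "+", ((1, 300),))
    (ev,) = _events([t1, t2], "IR")
    assert ev.introns == ((101, 200),)
    assert ev.inclusion_transcripts == {"T2"}
    assert ev.exclusion_transcripts == {"T1"}
    assert ev.first_intron  # intron 1 of the splicing transcript


def test_es_definitional():
    t1 = _mk("T1", "G", "+", ((1, 100), (151, 200), (251, 350)))
    t2 = _mk("T2", "G", "+", ((1, 100), (251, 350)))
    (ev,) = _events([t1, t2], "ES")
    assert ev.exon == (151, 200)
    assert ev.introns == ((101, 250),)
    assert ev.inclusion_transcripts == {"T1"}
    assert ev.exclusion_transcripts == {"T2"}


def test_a5_definitional_shared_acceptor():
    t1 = _mk("T1", "G", "+", ((1, 100), (201, 300)))   # intron 101-200
    t2 = _mk("T2", "G", "+", ((1, 120), (201, 300)))   # intron 121-200
    (ev,) = _events([t1, t2], "A5")
    assert set(ev.introns) == {(101, 200), (121, 200)}
    assert ev.inclusion_transcripts == {"T2"}  # shorter intron, more exon
    assert _events([t1, t2], "A3") == []


def test_a3_definitional_shared_donor():
    t1 = _mk("T1", "G", "+", ((1, 100), (201, 300)))   # intron 101-200
    t2 = _mk("T2", "G", "+", ((1, 100), (181, 300)))   # intron 101-180
    (ev,) = _events([t1, t2], "A3")
    assert set(ev.introns) == {(101, 200), (101, 180)}
    assert ev.inclusion_transcripts == {"T2"}
    assert _events([t1, t2], "A5") == []


def test_exitron_definitional():
    ref = _mk("T1", "G", "+", ((1, 300),), cds=((1, 300),))
    t2 = _mk("T2", "G", "+", ((1, 100), (201, 300)))
    models = mark_reference_isoforms([ref, t2])
    (ev,) = _events(models, "EX")
    assert ev.introns == ((101, 200),)
    assert ev.inclusion_transcripts == {"T1"}


def test_exitron_requires_cds():
    t1 = _mk("T1", "G", "+", ((1, 300),))
    t2 = _mk("T2", "G", "+", ((1, 100), (201, 300)))
    with pytest.raises(ValueError, match="CDS"):
        _events([t1, t2], "EX")


def test_single_isoform_gene_yields_nothing():
    t = _mk("T1", "G", "+", ((1, 100), (201, 300)))
    assert extract_all_events([t], enumerate_introns([t]), ["IR", "ES", "A5", "A3"]) == []


def test_extraction_order_independent():
    rng = np.random.default_rng(5)
    transcripts = random_annotation(rng, n_genes=5)
    introns = enumerate_introns(transcripts)
    base = {e.event_id for e in extract_all_events(transcripts, introns, ["IR", "ES", "A5", "A3"])}
    for seed in range(3):
        perm = list(transcripts)
        np.random.default_rng(seed).shuffle(perm)
        shuffled = {e.event_id for e in
                    extract_all_events(perm, enumerate_introns(perm), ["IR", "ES", "A5", "A3"])}
        assert shuffled == base


def test_ir_intron_disjoint_from_inclusion_junctions():
    rng = np.random.default_rng(9)
    transcripts = random_annotation(rng, n_genes=8)
    by_id = {t.transcript_id: t for t in transcripts}
    for ev in _events(transcripts, "IR"):
        s, e = ev.introns[0]
        for tid in ev.inclusion_transcripts:
            for js, je in by_id[tid].introns:
                assert je < s or js > e


@pytest.mark.parametrize("seed", range(25))
def test_oracle_equivalence_random_annotations(seed):
    """Extracted events match a brute-force all-isoform-pairs enumeration."""
    rng = np.random.default_rng(seed)
    transcripts = random_annotation(rng, n_genes=4)
    introns = enumerate_introns(transcripts)
    types = ["IR", "ES", "A5", "A3"]
    if any(t.cds for t in transcripts):
        types.append("EX")
    impl = implementation_keyed(extract_all_events(transcripts, introns, types))
    oracle = brute_force_events(transcripts)
    assert set(impl) == set(oracle)
    for key in oracle:
        assert impl[key]["inclusion"] == oracle[key]["inclusion"], key
        assert impl[key]["exclusion"] == oracle[key]["exclusion"], key
        if key[1] in ("IR", "EX"):
            assert impl[key]["first"] == oracle[key]["first"], key


def _mirror(transcripts, m):
    out = []
    for t in transcripts:
        exons = tuple(sorted((m - e, m - s) for s, e in t.exons))
        cds = tuple(sorted((m - e, m - s) for s, e in t.cds)) if t.cds else None
        out.append(TranscriptModel(t.transcript_id, t.gene_id, t.chrom,
                                   "-" if t.strand == "+" else "+", exons, cds,
                                   t.is_reference))
    return out


@pytest.mark.parametrize("seed", [1, 12, 33])
def test_strand_mirror_preserves_event_types(seed):
    """Reverse-complementing a locus maps A5->A5 and A3->A3 (definitions are
    transcript-orientation relative), and preserves all event counts."""
    rng = np.random.default_rng(seed)
    transcripts = random_annotation(rng, n_genes=5)
    m = max(e for t in transcripts for _, e in t.exons) + 100
    mirrored = _mirror(transcripts, m)
    introns = enumerate_introns(transcripts)
    introns_m = enumerate_introns(mirrored)
    for etype in ("IR", "ES", "A5", "A3"):
        fwd = extract_events(transcripts, introns, etype)
        rev = extract_events(mirrored, introns_m, etype)
        fwd_cores = sorted(tuple(sorted((m - e, m - s) for s, e in ev.introns))
                           for ev in fwd)
        rev_cores = sorted(tuple(sorted(ev.introns)) for ev in rev)
        assert fwd_cores == rev_cores
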