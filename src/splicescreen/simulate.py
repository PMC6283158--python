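"""Synthetic annotation, quantification, variant and PSM data with known truth.

The generator emulates the data structure of a mutagenesis splicing screen
analysed by RNA-seq and iTRAQ phosphoproteomics: a multi-isoform gene
annotation instantiating the five event types, triplicate per-condition
transcript TPM tables with logit-normal PSI replicate noise and planted
dPSI effects, EMS-style G/A -> C/T transition variants placed inside or
safely outside splice-site windows, and phosphopeptide PSM tables with
planted fold-change gains and losses.  Every generated event and
phosphosite is covered by a truth table, so each pipeline stage can be
benchmarked against known ground truth without external data.

All randomness flows through numpy's PCG64 generator seeded from
``SimConfig.seed``; identical configs produce byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import Intron, TranscriptModel, enumerate_introns, mark_reference_isoforms
from .events import SpliceEvent, extract_all_events
from .phospho import PhosphoMod, PsmRecord, notate_site
from .pwm import reverse_complement
from .windows import event_windows, splice_windows

BASES = "ACGT"


@dataclass
class SimConfig:
    """Generator parameters; defaults reflect the emulated study design
    (triplicate RNA-seq per genotype, |dPSI| = 0.3 effects in 10% of
    events, logit-scale PSI noise 0.05, EMS transition variants,
    three-replicate iTRAQ with two-fold phosphosite effects)."""

    seed: int
    # annotation
    n_genes: int = 60
    event_mix: dict = field(default_factory=lambda: {
        "IR": 0.55, "ES": 0.10, "A5": 0.15, "A3": 0.15, "EX": 0.05})
    bystander_fraction: float = 0.3   # genes receiving a third isoform
    ir_introns_range: tuple[int, int] = (1, 3)
    intron_length_range: tuple[int, int] = (60, 400)
    exon_length_range: tuple[int, int] = (80, 300)
    genome_gc: float = 0.36
    atac_fraction: float = 0.0
    # splicing effects & quantification
    frac_affected: float = 0.10
    effect_size: float = 0.3
    replicates: int = 3
    expr_log_mean: float = 4.0       # natural-log TPM of gene totals
    expr_log_sd: float = 1.0
    expression_noise_sd: float = 0.15
    psi_noise_sd: float = 0.05       # logit-scale replicate noise
    degrade_affected_donors: bool = False
    first_intron_affected_prob: float | None = None
    # variants
    n_variants_in_window: int = 5
    n_variants_out_window: int = 20
    n_indels_in_window: int = 0
    ems_fraction: float = 1.0
    # phospho
    n_sites: int = 300
    frac_sites_affected: float = 0.10
    fold_change: float = 2.0
    cv: float = 0.20
    phospho_replicates: int = 3
    ambiguous_fraction: float = 0.10
    multi_master_fraction: float = 0.10
    psms_per_site: tuple[int, int] = (1, 3)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("frac_affected", "atac_fraction", "ems_fraction",
                     "frac_sites_affected", "ambiguous_fraction",
                     "multi_master_fraction", "bystander_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class GeneSpec:
    gene_id: str
    chrom: str
    strand: str
    etype: str
    affected: bool
    psi_control: float
    psi_mutant: float
    designed_intron: tuple[int, int]
    first_intron: bool
    degrade_donor: bool = False


@dataclass
class SimulatedDataset:
    config: SimConfig
    transcripts: list[TranscriptModel]
    introns: list[Intron]
    events: list[SpliceEvent]
    genome: dict[str, str]
    proteins: dict[str, str]
    genes: list[GeneSpec]
    truth_events: pd.DataFrame
    truth_sites: pd.DataFrame | None = None
    truth_variants: pd.DataFrame | None = None
    psms: list[PsmRecord] | None = None
    variants: list | None = None
    tpm: pd.DataFrame | None = None
    design: pd.DataFrame | None = None
    paths: dict[str, Path] = field(default_factory=dict)


# splice-site sampling profiles in transcript orientation (probabilities
# over A,C,G,T per position; GT/AG dinucleotide positions are forced).
_DONOR_PROFILE = np.array(
    [[0.30, 0.15, 0.35, 0.20],   # exonic -3
     [0.55, 0.10, 0.15, 0.20],   # exonic -2
     [0.10, 0.05, 0.75, 0.10],   # exonic -1
     [0.00, 0.00, 1.00, 0.00],   # +1 G (forced)
     [0.00, 0.00, 0.00, 1.00],   # +2 T (forced)
     [0.55, 0.05, 0.10, 0.30],   # +3
     [0.60, 0.10, 0.10, 0.20],   # +4
     [0.15, 0.05, 0.55, 0.25],   # +5
     [0.20, 0.10, 0.15, 0.55],   # +6
     [0.25, 0.20, 0.20, 0.35],
     [0.25, 0.20, 0.20, 0.35],
     [0.25, 0.20, 0.20, 0.35],
     [0.25, 0.20, 0.20, 0.35]])

_ACCEPTOR_PROFILE = np.vstack([
    np.tile([0.15, 0.20, 0.10, 0.55], (10, 1)),   # polypyrimidine tract
    [[0.20, 0.30, 0.10, 0.40],
     [0.25, 0.25, 0.10, 0.40],
     [0.95, 0.02, 0.01, 0.02],                    # A of AG (forced below)
     [0.01, 0.01, 0.97, 0.01],                    # G of AG (forced below)
     [0.20, 0.15, 0.50, 0.15],                    # exonic +1
     [0.30, 0.20, 0.25, 0.25],
     [0.30, 0.20, 0.25, 0.25]]])

_UNIFORM = np.full(4, 0.25)


def _sample_site(profile: np.ndarray, rng: np.random.Generator,
                 forced: dict[int, str], degrade: bool = False) -> str:
    out = []
    for i in range(profile.shape[0]):
        if i in forced:
            out.append(forced[i])
        elif degrade:
            out.append(BASES[rng.choice(4, p=_UNIFORM)])
        else:
            out.append(BASES[rng.choice(4, p=profile[i] / profile[i].sum())])
    return "".join(out)


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def gen_annotation(config: SimConfig):
    """Build transcripts, genome and protein sequences with planted events.

    Returns ``(transcripts, genome, proteins, genes)``; the genome carries
    sampled donor/acceptor site sequences (GT-AG by default, AT-AC for a
    configured fraction) at every planted intron boundary.
    """
    rng = np.random.default_rng([config.seed, 1])
    types = sorted(config.event_mix)
    mix = np.array([config.event_mix[t] for t in types], dtype=float)
    mix = mix / mix.sum()

    transcripts: list[TranscriptModel] = []
    genes: list[GeneSpec] = []
    chrom = "chr1"
    cursor = 1001

    def ilen():
        return int(rng.integers(*config.intron_length_range))

    def elen():
        return int(rng.integers(*config.exon_length_range))

    for g in range(config.n_genes):
        gene_id = f"G{g + 1:04d}"
        etype = types[rng.choice(len(types), p=mix)]
        strand = "+" if rng.random() < 0.5 else "-"
        affected = rng.random() < config.frac_affected
        # control PSI in a band leaving room for the planted shift
        up = rng.random() < 0.5
        if affected:
            lo, hi = (0.15, 0.95 - config.effect_size) if up else (0.05 + config.effect_size, 0.85)
            psi_c = float(rng.uniform(lo, hi))
            psi_m = psi_c + (config.effect_size if up else -config.effect_size)
        else:
            psi_c = float(rng.uniform(0.15, 0.85))
            psi_m = psi_c

        a = cursor + 30  # leave room for the bystander TSS extension
        tx: list[tuple[str, tuple, tuple | None]] = []
        designed = None
        first_flag = False

        if etype in ("IR", "EX"):
            if etype == "IR":
                n_int = int(rng.integers(config.ir_introns_range[0],
                                         config.ir_introns_range[1] + 1))
            else:
                n_int = 1
            exons = []
            pos = a
            for _ in range(n_int + 1):
                e = elen()
                exons.append((pos, pos + e - 1))
                pos = pos + e + ilen()
            spliced = tuple(exons)
            tx_introns = [(spliced[i][1] + 1, spliced[i + 1][0] - 1) for i in range(n_int)]
            # retained intron: transcript-orientation ordinal
            if affected and config.first_intron_affected_prob is not None \
                    and rng.random() < config.first_intron_affected_prob:
                ordinal = 1
            else:
                ordinal = int(rng.integers(1, n_int + 1))
            gidx = ordinal - 1 if strand == "+" else n_int - ordinal
            designed = tx_introns[gidx]
            first_flag = ordinal == 1
            # retaining isoform: merge exons around the retained intron
            retained = list(spliced)
            retained[gidx] = (retained[gidx][0], retained[gidx + 1][1])
            del retained[gidx + 1]
            cds = None
            if etype == "EX":
                # single-exon reference whose CDS strictly contains the intron
                retained = [(a, spliced[-1][1])]
                cds = ((a + 10, spliced[-1][1] - 10),)
                designed = tx_introns[0]
                first_flag = True
            tx.append((f"{gene_id}.1", tuple(retained), cds))
            tx.append((f"{gene_id}.2", spliced, None))

        elif etype == "ES":
            e1, e2, e3 = elen(), elen(), elen()
            i1, i2 = ilen(), ilen()
            x1 = (a, a + e1 - 1)
            x2 = (x1[1] + i1 + 1, x1[1] + i1 + e2)
            x3 = (x2[1] + i2 + 1, x2[1] + i2 + e3)
            tx.append((f"{gene_id}.1", (x1, x2, x3), None))
            tx.append((f"{gene_id}.2", (x1, x3), None))
            designed = (x1[1] + 1, x3[0] - 1)  # the skipping junction

        else:  # A5 / A3
            e1, e2 = elen(), elen()
            gap = ilen() + 60
            shift = int(rng.integers(20, 50))
            x1 = (a, a + e1 - 1)
            x2 = (x1[1] + gap + 1, x1[1] + gap + e2)
            # variable boundary: donor side for A5, acceptor side for A3,
            # in transcript orientation
            vary_start = (etype == "A3") == (strand == "+")
            if vary_start:
                # different genomic starts of exon2 (intron ends differ)
                long_x2 = x2
                short_x2 = (x2[0] - shift, x2[1])
                tx.append((f"{gene_id}.1", (x1, short_x2), None))
                tx.append((f"{gene_id}.2", (x1, long_x2), None))
                designed = (x1[1] + 1, short_x2[0] - 1)  # the shorter intron
            else:
                # different genomic ends of exon1 (intron starts differ)
                long_x1 = x1
                short_x1 = (x1[0], x1[1] + shift)
                tx.append((f"{gene_id}.1", (short_x1, x2), None))
                tx.append((f"{gene_id}.2", (long_x1, x2), None))
                designed = (short_x1[1] + 1, x2[0] - 1)

        if rng.random() < config.bystander_fraction:
            # extra isoform: the exclusion isoform with an upstream-extended
            # outermost exon (alternative TSS); creates no new events
            tid, exons, _ = tx[1]
            ext = ((exons[0][0] - 30, exons[0][1]),) + exons[1:]
            tx.append((f"{gene_id}.3", ext, None))

        for tid, exons, cds in tx:
            transcripts.append(TranscriptModel(tid, gene_id, chrom, strand, exons, cds))
        genes.append(GeneSpec(gene_id, chrom, strand, etype, affected,
                              psi_c, psi_m, designed, first_flag,
                              degrade_donor=(affected and config.degrade_affected_donors
                                             and etype == "IR")))
        cursor = max(e for _, exons, _ in tx for _, e in exons) + 500

    transcripts = mark_reference_isoforms(transcripts)

    # genome background
    gc = config.genome_gc
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    length = cursor + 1000
    seq = np.array(list(BASES), dtype="U1")[rng.choice(4, size=length, p=probs)]

    # plant splice-site sequences at every distinct intron
    introns = enumerate_introns(transcripts)
    degrade_introns = {(g.chrom, g.designed_intron) for g in genes if g.degrade_donor}
    for intr in introns:
        atac = rng.random() < config.atac_fraction
        d1, d2 = ("A", "T") if atac else ("G", "T")
        a1, a2 = ("A", "C") if atac else ("A", "G")
        degrade = (intr.chrom, (intr.start, intr.end)) in degrade_introns
        donor = _sample_site(_DONOR_PROFILE, rng, {3: d1, 4: d2}, degrade=degrade)
        acceptor = _sample_site(_ACCEPTOR_PROFILE, rng, {12: a1, 13: a2})
        w5, w3 = splice_windows(intr)
        for w, site in ((w5, donor), (w3, acceptor)):
            placed = site if intr.strand == "+" else reverse_complement(site)
            seq[w.start - 1 : w.end] = list(placed)

    genome = {chrom: "".join(seq)}

    # one protein per gene, named after the reference isoform
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"), dtype="U1")
    weights = np.array([7, 2, 5, 6, 4, 7, 2, 5, 6, 9, 2, 4, 5, 4, 5, 9, 6, 6, 1, 3], float)
    weights /= weights.sum()
    proteins = {}
    for g in genes:
        n = int(rng.integers(250, 400))
        proteins[f"{g.gene_id}.1"] = "".join(aa[rng.choice(20, size=n, p=weights)])
    return transcripts, genome, proteins, genes


def _true_fractions(gene_tx: list[str], psi: float) -> dict[str, float]:
    """True isoform fractions: .1 carries the inclusion mass, the exclusion
    mass is split 0.7/0.3 between .2 and a bystander .3 when present."""
    fracs = {}
    for tid in gene_tx:
        if tid.endswith(".1"):
            fracs[tid] = psi
        elif tid.endswith(".2"):
            fracs[tid] = (1 - psi) * (0.7 if len(gene_tx) > 2 else 1.0)
        else:
            fracs[tid] = (1 - psi) * 0.3
    return fracs


def build_truth_events(events: list[SpliceEvent], genes: list[GeneSpec]) -> pd.DataFrame:
    """Per-event truth derived from the gene-level true isoform fractions."""
    by_gene = {g.gene_id: g for g in genes}
    rows = []
    for ev in events:
        g = by_gene[ev.gene_id]
        tx = sorted(ev.transcripts)
        truth = {}
        for cond, psi in (("control", g.psi_control), ("mutant", g.psi_mutant)):
            fr = _true_fractions(tx, psi)
            inc = sum(fr[t] for t in ev.inclusion_transcripts)
            tot = inc + sum(fr[t] for t in ev.exclusion_transcripts)
            truth[cond] = inc / tot
        rows.append({
            "event_id": ev.event_id, "type": ev.type, "gene_id": ev.gene_id,
            "psi_control": truth["control"], "psi_mutant": truth["mutant"],
            "delta_psi": truth["mutant"] - truth["control"],
            "affected": g.affected, "first_intron": ev.first_intron,
        })
    return pd.DataFrame(rows)


def gen_quant(transcripts: list[TranscriptModel], genes: list[GeneSpec],
              config: SimConfig):
    """Per-sample transcript TPMs: gene totals are log-normal, isoform
    splits follow a logit-normal draw around the condition's true PSI.

    Returns ``(tpm_frame, design_frame)`` with one column per sample.
    """
    rng = np.random.default_rng([config.seed, 2])
    by_gene: dict[str, list[str]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t.transcript_id)

    samples = [f"{cond}_{r}" for cond in ("control", "mutant")
               for r in range(1, config.replicates + 1)]
    design = pd.DataFrame({
        "sample": samples,
        "condition": [s.rsplit("_", 1)[0] for s in samples],
        "replicate": [int(s.rsplit("_", 1)[1]) for s in samples],
    })

    tids = sorted(t.transcript_id for t in transcripts)
    data = pd.DataFrame(0.0, index=tids, columns=samples)
    for g in genes:
        gene_tx = sorted(by_gene[g.gene_id])
        base = float(rng.lognormal(config.expr_log_mean, config.expr_log_sd))
        for s in samples:
            cond = s.rsplit("_", 1)[0]
            true_psi = g.psi_control if cond == "control" else g.psi_mutant
            if config.psi_noise_sd > 0:
                x = _logit(true_psi) + float(rng.normal(0, config.psi_noise_sd))
                sample_psi = 1.0 / (1.0 + math.exp(-x))
            else:
                sample_psi = true_psi
            total = base * float(rng.lognormal(0, config.expression_noise_sd)) \
                if config.expression_noise_sd > 0 else base
            for tid, frac in _true_fractions(gene_tx, sample_psi).items():
                data.at[tid, s] = total * frac
    return data, design


@dataclass(frozen=True)
class SimVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    in_window: bool


def gen_variants(events: list[SpliceEvent], genome: dict[str, str],
                 genes: list[GeneSpec], config: SimConfig):
    """Plant SNPs/indels inside splice windows of chosen events and safely
    outside all windows elsewhere.

    Returns ``(variants, truth_frame)`` where the truth lists, per event,
    whether any planted variant overlaps one of its windows (computed here
    by direct interval arithmetic, independently of the masking module).
    """
    rng = np.random.default_rng([config.seed, 3])
    chrom = genes[0].chrom if genes else "chr1"
    seq = genome[chrom]

    windows = {ev.event_id: [(w.start, w.end) for w in event_windows(ev)]
               for ev in events}

    variants: list[SimVariant] = []
    order = rng.permutation(len(events))
    n_snp = min(config.n_variants_in_window, len(events))
    chosen = [events[i] for i in order[:n_snp + config.n_indels_in_window]]
    for j, ev in enumerate(chosen):
        ws, we = windows[ev.event_id][int(rng.integers(len(windows[ev.event_id])))]
        if j < n_snp:
            ems = rng.random() < config.ems_fraction
            positions = list(range(ws, we + 1))
            rng.shuffle(positions)
            pos = next((p for p in positions if not ems or seq[p - 1] in "GC"), positions[0])
            ref = seq[pos - 1]
            alt = {"G": "A", "C": "T"}.get(ref, "C" if ref != "C" else "G") if ems \
                else {"A": "C", "C": "G", "G": "T", "T": "A"}[ref]
            variants.append(SimVariant(chrom, pos, ref, alt, True))
        else:
            # deletion straddling the window's left edge
            pos = ws - 2
            variants.append(SimVariant(chrom, pos, seq[pos - 1 : pos + 3], seq[pos - 1], True))

    # out-of-window SNPs: drawn from the gaps between splice windows, kept
    # at least 60 bp away from every window edge
    all_windows = sorted(w for ws_ in windows.values() for w in ws_)
    free = []
    prev_end = 0
    for ws, we in all_windows:
        if ws - prev_end > 120:
            free.append((prev_end + 60, ws - 60))
        prev_end = max(prev_end, we)
    free.append((prev_end + 60, len(seq) - 10))
    free = [iv for iv in free if iv[1] > iv[0]]
    for _ in range(config.n_variants_out_window):
        lo, hi = free[int(rng.integers(len(free)))]
        pos = int(rng.integers(lo, hi + 1))
        ems = rng.random() < config.ems_fraction
        ref = seq[pos - 1]
        if ems and ref not in "GC":
            # walk to the nearest G/C still inside the free interval
            for off in range(1, 50):
                if pos + off <= hi and seq[pos + off - 1] in "GC":
                    pos, ref = pos + off, seq[pos + off - 1]
                    break
        alt = {"G": "A", "C": "T"}.get(ref, {"A": "C", "T": "A"}.get(ref, "A"))
        variants.append(SimVariant(chrom, pos, ref, alt, False))

    variants.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))

    rows = []
    for ev in events:
        hit = any(
            v.pos <= we and v.pos + len(v.ref) - 1 >= ws
            for ws, we in windows[ev.event_id] for v in variants
        )
        rows.append({"event_id": ev.event_id, "masked": hit})
    return variants, pd.DataFrame(rows)


def _tryptic_peptides(protein: str):
    """Fragments from cutting after K/R, with their 1-based start."""
    out, start = [], 0
    for i, aa in enumerate(protein):
        if aa in "KR":
            out.append((start + 1, protein[start : i + 1]))
            start = i + 1
    if start < len(protein):
        out.append((start + 1, protein[start:]))
    return out


def gen_psm_table(config: SimConfig, proteins: dict[str, str]):
    """PSM records with planted phosphosite gains/losses.

    Returns ``(psms, truth_frame)``; the truth lists each site's notation,
    affected flag, direction and fold change.
    """
    rng = np.random.default_rng([config.seed, 4])
    candidates = []
    for acc in sorted(proteins):
        for start, pep in _tryptic_peptides(proteins[acc]):
            if 7 <= len(pep) <= 25 and any(r in pep for r in "STY"):
                candidates.append((acc, start, pep))
    n_sites = config.n_sites
    if len(candidates) < n_sites:
        import warnings

        warnings.warn(
            f"only {len(candidates)} candidate peptides available; generating "
            f"{len(candidates)} phosphosites instead of {n_sites}"
        )
        n_sites = len(candidates)
    if n_sites == 0:
        raise ValueError("no candidate phosphopeptides; increase n_genes")
    picks = rng.choice(len(candidates), size=n_sites, replace=False)
    sigma = math.sqrt(math.log(1.0 + config.cv ** 2))

    psms: list[PsmRecord] = []
    truth_rows = []
    for site_idx in sorted(picks):
        acc, start, pep = candidates[site_idx]
        ambiguous = rng.random() < config.ambiguous_fraction
        st_positions = [i + 1 for i, a in enumerate(pep) if a in "ST"]
        if ambiguous and len(st_positions) >= 2:
            residues = tuple(sorted({pep[i - 1] for i in st_positions}))
            mod = PhosphoMod(residues)
        else:
            sty = [i + 1 for i, a in enumerate(pep) if a in "STY"]
            ppos = int(sty[rng.integers(len(sty))])
            mod = PhosphoMod((pep[ppos - 1],), ppos, 100.0)

        masters = [acc]
        starts = {acc: start}
        if rng.random() < config.multi_master_fraction:
            for j in range(int(rng.integers(1, 3))):
                extra = f"{acc}.m{j + 1}"
                masters.append(extra)
                starts[extra] = start + int(rng.integers(1, 20))

        affected = rng.random() < config.frac_sites_affected
        direction = int(rng.choice([-1, 1])) if affected else 0
        fold = config.fold_change ** direction if affected else 1.0
        base = float(rng.lognormal(math.log(5e4), 1.0))

        template = PsmRecord(pep, [mod], masters, 1.0, 1.0, 1, starts)
        notation = notate_site(template)
        truth_rows.append({"site": notation, "affected": affected,
                           "direction": {1: "gain", -1: "loss", 0: ""}[direction],
                           "fold": fold})

        for rep in range(1, config.phospho_replicates + 1):
            n_psm = int(rng.integers(config.psms_per_site[0], config.psms_per_site[1] + 1))
            for _ in range(n_psm):
                c = base / n_psm * float(rng.lognormal(0, sigma))
                t = base / n_psm * fold * float(rng.lognormal(0, sigma))
                psms.append(PsmRecord(pep, [mod], masters, c, t, rep, dict(starts),
                                      preceding="K", following="A"))
    return psms, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# file writers

def write_gtf(transcripts: list[TranscriptModel], path: Path, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"##synthetic annotation; generator=splicescreen PCG64 seed={seed}\n")
        for t in sorted(transcripts, key=lambda x: (x.chrom, x.span[0], x.transcript_id)):
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            for s, e in t.exons:
                fh.write(f"{t.chrom}\tsim\texon\t{s}\t{e}\t.\t{t.strand}\t.\t{attrs}\n")
            for s, e in t.cds or ():
                fh.write(f"{t.chrom}\tsim\tCDS\t{s}\t{e}\t.\t{t.strand}\t0\t{attrs}\n")


def write_fasta(seqs: dict[str, str], path: Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_vcf(variants: list[SimVariant], genome: dict[str, str], path: Path,
              seed: int) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=splicescreen-sim seed={seed}\n")
        for chrom in sorted(genome):
            fh.write(f"##contig=<ID={chrom},length={len(genome[chrom])}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t100\tPASS\t.\n")


def write_quant(tpm: pd.DataFrame, design: pd.DataFrame, out_dir: Path) -> None:
    qdir = out_dir / "quant"
    qdir.mkdir(parents=True, exist_ok=True)
    for sample in design["sample"]:
        with open(qdir / f"{sample}.tsv", "w") as fh:
            fh.write("Name\tTPM\n")
            for tid, v in tpm[sample].items():
                fh.write(f"{tid}\t{v:.6f}\n")
    design.to_csv(out_dir / "design.tsv", sep="\t", index=False)


def write_psm_table(psms: list[PsmRecord], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("peptide\tmodifications\tmaster_proteins\tpeptide_start\t"
                 "abundance_control\tabundance_treatment\treplicate\n")
        for p in psms:
            mod = p.modification[0]
            if mod.ambiguous:
                mod_str = "Phospho [" + "/".join(mod.residues) + "]"
            else:
                score = f"({mod.score:g})" if mod.score is not None else ""
                mod_str = f"Phospho [{mod.residues[0]}{mod.position}{score}]"
            fh.write("\t".join([
                p.peptide, mod_str, ";".join(p.master_proteins),
                ";".join(str(p.peptide_start[a]) for a in p.master_proteins),
                f"{p.abundance_control:.4f}", f"{p.abundance_treatment:.4f}",
                str(p.replicate),
            ]) + "\n")


def simulate(config: SimConfig, out_dir: str | Path | None = None) -> SimulatedDataset:
    """Run every generator stage; optionally write all standard-format files."""
    transcripts, genome, proteins, genes = gen_annotation(config)
    introns = enumerate_introns(transcripts)
    types = ["IR", "ES", "A5", "A3"] + (["EX"] if any(t.cds for t in transcripts) else [])
    events = extract_all_events(transcripts, introns, types)
    truth_events = build_truth_events(events, genes)
    tpm, design = gen_quant(transcripts, genes, config)
    variants, truth_variants = gen_variants(events, genome, genes, config)
    psms, truth_sites = gen_psm_table(config, proteins)

    ds = SimulatedDataset(
        config=config, transcripts=transcripts, introns=introns, events=events,
        genome=genome, proteins=proteins, genes=genes,
        truth_events=truth_events, truth_sites=truth_sites,
        truth_variants=truth_variants, psms=psms, variants=variants,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gtf": out_dir / "annotation.gtf",
            "genome": out_dir / "genome.fa",
            "proteins": out_dir / "proteins.fa",
            "vcf": out_dir / "variants.vcf",
            "psm": out_dir / "psm.tsv",
            "design": out_dir / "design.tsv",
            "quant_dir": out_dir / "quant",
            "truth_events": out_dir / "truth_events.tsv",
            "truth_sites": out_dir / "truth_sites.tsv",
            "truth_variants": out_dir / "truth_variants.tsv",
        }
        write_gtf(transcripts, paths["gtf"], config.seed)
        write_fasta(genome, paths["genome"])
        write_fasta(proteins, paths["proteins"])
        write_vcf(variants, genome, paths["vcf"], config.seed)
        write_quant(tpm, design, out_dir)
        write_psm_table(psms, paths["psm"])
        truth_events.to_csv(paths["truth_events"], sep="\t", index=False, float_format="%.6f")
        truth_sites.to_csv(paths["truth_sites"], sep="\t", index=False, float_format="%.6f")
        truth_variants.to_csv(paths["truth_variants"], sep="\t", index=False)
        ds.paths = paths
    ds.tpm = tpm
    ds.design = design
    return ds
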