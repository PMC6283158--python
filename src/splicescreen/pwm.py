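"""Position weight matrices for splice-site strength, plus sequence features.

Matrices are trained on aligned splice-site windows (13 nt donor, 17 nt
acceptor — the same geometry used for variant masking) with a pseudocount
over a uniform background, and sites are scored as the sum of per-position
log2-odds.  A normalised percent-of-range score in [0, 100] is reported
alongside the raw sum so scores are comparable across matrices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pyfaidx import Fasta

from .annotation import Intron
from .windows import (FIVE_PRIME_WIDTH, THREE_PRIME_WIDTH, five_prime_window,
                      splice_windows, three_prime_window)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

SIDE_WIDTH = {"five_prime": FIVE_PRIME_WIDTH, "three_prime": THREE_PRIME_WIDTH}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """GC fraction of a nucleotide string; N bases are ignored entirely."""
    seq = seq.upper()
    counts = {b: seq.count(b) for b in BASES}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("cannot compute GC content of an empty or all-N sequence")
    return (counts["G"] + counts["C"]) / denom


@dataclass
class PWM:
    """Log2-odds position weight matrix over a uniform background."""

    side: str
    width: int
    weights: np.ndarray  # (width, 4), order A C G T
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.width, 4):
            raise ValueError(f"weights shape {self.weights.shape} != ({self.width}, 4)")
        if not np.isfinite(self.weights).all():
            raise ValueError("PWM weights must be finite")

    @property
    def min_score(self) -> float:
        return float(self.weights.min(axis=1).sum())

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.weights.argmax(axis=1))

    def anticonsensus(self) -> str:
        return "".join(BASES[i] for i in self.weights.argmin(axis=1))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# side=%s width=%d\n" % (self.side, self.width))
            fh.write("position\t" + "\t".join(BASES) + "\n")
            for i, row in enumerate(self.weights, start=1):
                fh.write(f"{i}\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PWM":
        side, width, rows = "five_prime", None, []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    for tok in line[1:].split():
                        k, _, v = tok.partition("=")
                        if k == "side":
                            side = v
                        elif k == "width":
                            width = int(v)
                    continue
                if line.startswith("position") or not line:
                    continue
                rows.append([float(x) for x in line.split("\t")[1:5]])
        weights = np.array(rows)
        return cls(side=side, width=width or len(rows), weights=weights)


def build_pwm(sites: list[str], side: str, pseudocount: float = 0.5) -> PWM:
    """Train a PWM from aligned site sequences.

    Per-position probabilities are ``(n_b + c) / (N + 4c)`` with pseudocount
    ``c``; weights are log2 over the uniform 0.25 background.  Sites
    containing non-ACGT characters are excluded from training.
    """
    width = SIDE_WIDTH[side]
    clean = []
    for s in sites:
        s = s.upper()
        if len(s) != width:
            raise ValueError(f"site length {len(s)} != expected width {width} for {side}")
        if all(b in _BASE_INDEX for b in s):
            clean.append(s)
    if not clean:
        raise ValueError("no unambiguous training sites")
    counts = np.zeros((width, 4))
    for s in clean:
        for i, b in enumerate(s):
            counts[i, _BASE_INDEX[b]] += 1
    n = len(clean)
    probs = (counts + pseudocount) / (n + 4 * pseudocount)
    weights = np.log2(probs / 0.25)
    return PWM(side=side, width=width, weights=weights,
               metadata={"n_sites": n, "pseudocount": pseudocount, "background": "uniform"})


def score_site(pwm: PWM, seq: str) -> tuple[float, float]:
    """Score one site: ``(raw log2-odds sum, percent-of-range in [0, 100])``.

    Ambiguous bases give ``(nan, nan)`` with a warning.
    """
    seq = seq.upper()
    if len(seq) != pwm.width:
        raise ValueError(f"sequence length {len(seq)} != PWM width {pwm.width}")
    if any(b not in _BASE_INDEX for b in seq):
        warnings.warn(f"ambiguous base in site {seq!r}; score is NA")
        return math.nan, math.nan
    raw = float(sum(pwm.weights[i, _BASE_INDEX[b]] for i, b in enumerate(seq)))
    lo, hi = pwm.min_score, pwm.max_score
    norm = 100.0 * (raw - lo) / (hi - lo) if hi > lo else 100.0
    return raw, norm


def extract_site_sequences(intron: Intron | tuple, genome: Fasta | dict) -> tuple[str, str]:
    """Donor (13 nt) and acceptor (17 nt) window sequences in transcript orientation.

    On the minus strand the genomic window sequences are reverse
    complemented, so e.g. a GT-AG intron always shows GT at donor positions
    4-5 and AG at acceptor positions 13-14.
    """
    w5, w3 = splice_windows(intron)
    five = _fetch(genome, w5.chrom, w5.start, w5.end)
    three = _fetch(genome, w3.chrom, w3.start, w3.end)
    if w5.strand == "-":
        five, three = reverse_complement(five), reverse_complement(three)
    return five, three


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    rec = genome[chrom]
    length = len(rec)
    if start < 1 or end > length:
        raise ValueError(f"window {chrom}:{start}-{end} exceeds contig bounds (len {length})")
    piece = rec[start - 1 : end]
    return str(piece).upper()


def intron_dinucleotides(intron: Intron | tuple, genome) -> tuple[str, str]:
    """Terminal dinucleotides in transcript orientation, e.g. ('GT', 'AG')."""
    five, three = extract_site_sequences(intron, genome)
    return five[3:5], three[12:14]


def train_pwms_from_annotation(
    introns: list[Intron], genome, canonical_only: bool = True,
    pseudocount: float = 0.5,
) -> tuple[PWM, PWM]:
    """Train donor and acceptor PWMs on the annotation's introns.

    With ``canonical_only`` only GT-AG introns contribute, which keeps the
    matrices from being diluted by minor-class or non-canonical sites.
    """
    fives, threes = [], []
    for intr in introns:
        try:
            five, three = extract_site_sequences(intr, genome)
        except ValueError:
            continue
        if canonical_only and (five[3:5] != "GT" or three[12:14] != "AG"):
            continue
        fives.append(five)
        threes.append(three)
    return build_pwm(fives, "five_prime", pseudocount), build_pwm(threes, "three_prime", pseudocount)
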