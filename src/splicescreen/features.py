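"""Intron feature records: length, GC content and splice-site strength."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .annotation import Intron
from .pwm import PWM, extract_site_sequences, gc_content, score_site


@dataclass
class IntronFeatureRecord:
    chrom: str
    strand: str
    start: int
    end: int
    length: int
    gc: float
    score5_raw: float
    score5_norm: float
    score3_raw: float
    score3_norm: float
    groups: list[str] = field(default_factory=list)


def intron_features(
    introns: list[Intron], genome, pwm5: PWM, pwm3: PWM,
    groups: dict[tuple, list[str]] | None = None,
) -> pd.DataFrame:
    """Per-intron feature table.

    ``groups`` optionally maps ``(chrom, start, end)`` keys to group labels
    (e.g. more_retained / less_retained / unchanged, or first / remaining)
    for downstream comparisons.  Introns whose windows fall off the contig
    score NaN.
    """
    rows = []
    for intr in introns:
        try:
            five, three = extract_site_sequences(intr, genome)
            s5 = score_site(pwm5, five)
            s3 = score_site(pwm3, three)
            intron_seq = _intron_sequence(intr, genome)
            gc = gc_content(intron_seq)
        except ValueError:
            s5 = s3 = (math.nan, math.nan)
            gc = math.nan
        labels = (groups or {}).get((intr.chrom, intr.start, intr.end), [])
        rows.append({
            "chrom": intr.chrom, "strand": intr.strand,
            "start": intr.start, "end": intr.end, "length": intr.length,
            "gc": gc,
            "score5_raw": s5[0], "score5_norm": s5[1],
            "score3_raw": s3[0], "score3_norm": s3[1],
            "groups": ";".join(labels),
        })
    return pd.DataFrame(rows)


def _intron_sequence(intr: Intron, genome) -> str:
    rec = genome[intr.chrom]
    if intr.end > len(rec) or intr.start < 1:
        raise ValueError(f"intron {intr.chrom}:{intr.start}-{intr.end} exceeds contig")
    return str(rec[intr.start - 1 : intr.end]).upper()
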