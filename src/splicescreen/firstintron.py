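"""First-intron analysis of differentially retained introns.

Differentially retained IR events are split into first introns (the
5'-most intron of at least one transcript that splices them, strand-aware)
versus all remaining introns.  Retention (mean event PSI in a genotype)
is compared between the two groups, and the observed first-intron share is
tested against the annotation-wide expectation with a 1-df chi-square
goodness-of-fit test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy import stats as sps

from .events import SpliceEvent
from .psi import CONTROL, MUTANT, PsiRecord
from .stats import GroupComparison, chi_square_gof, compare_groups


@dataclass
class FirstIntronPartition:
    first: set[str]
    remaining: set[str]
    annotation_first_fraction: float

    def __post_init__(self) -> None:
        if self.first & self.remaining:
            raise ValueError("first and remaining event sets overlap")
        if not 0.0 <= self.annotation_first_fraction <= 1.0:
            raise ValueError("annotation_first_fraction must be in [0, 1]")


@dataclass
class EnrichmentResult:
    observed_first: int
    observed_remaining: int
    expected_first_fraction: float
    chi_square: float
    df: int
    p_value: float
    binomial_p_value: float | None = None


def partition_ir(
    regulated_events: list[SpliceEvent],
    annotation_events: list[SpliceEvent],
) -> FirstIntronPartition:
    """Split regulated IR events by the first-intron flag.

    ``annotation_events`` must be the full annotated IR event set; the
    expected first-intron fraction is computed over ALL annotated IR
    events, not only the regulated ones.
    """
    if not regulated_events:
        raise ValueError("empty regulated event set")
    first = {e.event_id for e in regulated_events if e.first_intron}
    remaining = {e.event_id for e in regulated_events if not e.first_intron}
    ann_ir = [e for e in annotation_events if e.type == "IR"]
    if not ann_ir:
        raise ValueError("annotation event set contains no IR events")
    frac = sum(e.first_intron for e in ann_ir) / len(ann_ir)
    return FirstIntronPartition(first, remaining, frac)


def retention_comparison(
    partition: FirstIntronPartition,
    psi_records: list[PsiRecord],
    genotype: str = MUTANT,
) -> GroupComparison:
    """Wilcoxon rank-sum on per-event mean retention, first vs remaining.

    Retention of an IR event is its mean PSI (inclusion = retained form)
    in the requested genotype.
    """
    if genotype not in (CONTROL, MUTANT):
        raise ValueError(f"genotype must be {CONTROL!r} or {MUTANT!r}")
    by_id = {r.event_id: r for r in psi_records}
    first_vals = [by_id[e].mean_psi_by_condition[genotype]
                  for e in partition.first if e in by_id]
    rem_vals = [by_id[e].mean_psi_by_condition[genotype]
                for e in partition.remaining if e in by_id]
    return compare_groups(first_vals, rem_vals, test="wilcoxon",
                          names=("first", "remaining"))


def first_intron_enrichment(
    partition: FirstIntronPartition | tuple[int, int],
    expected_first_fraction: float | None = None,
) -> EnrichmentResult:
    """Chi-square goodness of fit of (first, remaining) counts.

    Accepts either a partition (using its annotation-wide fraction) or a
    raw ``(observed_first, observed_remaining)`` pair with an explicit
    expected fraction.  When an expected cell count falls below 5 the
    chi-square approximation is flagged and an exact binomial p-value is
    reported alongside.
    """
    if isinstance(partition, FirstIntronPartition):
        obs = (len(partition.first), len(partition.remaining))
        p = expected_first_fraction if expected_first_fraction is not None \
            else partition.annotation_first_fraction
    else:
        obs = tuple(partition)
        if expected_first_fraction is None:
            raise ValueError("expected_first_fraction required with raw counts")
        p = expected_first_fraction
    if sum(obs) == 0:
        raise ValueError("no observed events")
    if not 0.0 < p < 1.0:
        raise ValueError("expected fraction must be in (0, 1)")
    chi2, pval = chi_square_gof(obs, (p, 1.0 - p))
    n = sum(obs)
    binom_p = None
    if min(n * p, n * (1 - p)) < 5:
        warnings.warn("expected count < 5; chi-square approximation unreliable, "
                      "reporting exact binomial p-value alongside")
        binom_p = float(sps.binomtest(obs[0], n, p).pvalue)
    return EnrichmentResult(
        observed_first=obs[0], observed_remaining=obs[1],
        expected_first_fraction=p, chi_square=chi2, df=1, p_value=pval,
        binomial_p_value=binom_p,
    )
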