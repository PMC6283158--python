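"""Mendelian segregation: cross expectations, conditioning, and tests.

Genotype distributions are computed by exhaustive gamete enumeration under
independent assortment with exact rational probabilities.  A hemizygous
T-DNA insertion is modelled as a presence/absence allele pair such as
``("T", "-")``; a reporter-positive phenotype then means carrying at least
one ``T`` allele.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Mapping, Sequence

from scipy import stats as sps

from .stats import GroupComparison

Alleles = tuple[str, str]
Genotype = dict[str, Alleles]


def _allele_key(a: str) -> tuple[int, str]:
    # uppercase alleles sort first, then lowercase, then presence/absence '-'
    if a == "-":
        return (2, a)
    return (0, a) if a[:1].isupper() else (1, a)


def canonical_genotype(genotype: Mapping[str, Alleles], loci: Sequence[str]) -> str:
    """Canonical string form: alleles uppercase-first per locus, loci in order."""
    parts = []
    for locus in loci:
        a, b = sorted(genotype[locus], key=_allele_key)
        parts.append(f"{a}/{b}")
    return ";".join(parts)


@dataclass
class CrossSpec:
    """Two parental genotypes over named loci, assorting independently."""

    loci: list[str]
    parent1: Genotype
    parent2: Genotype

    def __post_init__(self) -> None:
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("locus names must be unique")
        for parent in (self.parent1, self.parent2):
            for locus in self.loci:
                if locus not in parent or len(parent[locus]) != 2:
                    raise ValueError(f"each parent needs exactly 2 alleles at locus {locus}")


class GenotypeDistribution(dict):
    """Map canonical genotype string -> exact probability (Fraction)."""

    def __init__(self, probs: Mapping[str, Fraction], loci: Sequence[str]):
        super().__init__(probs)
        self.loci = list(loci)
        total = sum(self.values())
        if total != 1:
            raise ValueError(f"probabilities sum to {total}, not 1")

    def marginal(self, locus: str) -> "GenotypeDistribution":
        idx = self.loci.index(locus)
        out: dict[str, Fraction] = {}
        for g, p in self.items():
            key = g.split(";")[idx]
            out[key] = out.get(key, Fraction(0)) + p
        return GenotypeDistribution(out, [locus])


def parse_genotype(text: str, loci: Sequence[str]) -> Genotype:
    """Parse e.g. ``"T/-;B/b"`` against an ordered locus list."""
    parts = text.split(";")
    if len(parts) != len(loci):
        raise ValueError(f"genotype {text!r} has {len(parts)} loci, expected {len(loci)}")
    return {locus: tuple(p.split("/")) for locus, p in zip(loci, parts)}


def cross(parent1: Genotype | str, parent2: Genotype | str,
          loci: Sequence[str]) -> GenotypeDistribution:
    """Offspring genotype distribution from two parents (Punnett enumeration)."""
    if isinstance(parent1, str):
        parent1 = parse_genotype(parent1, loci)
    if isinstance(parent2, str):
        parent2 = parse_genotype(parent2, loci)
    n = len(loci)
    half = Fraction(1, 2)
    out: dict[str, Fraction] = {}
    for picks1 in itertools.product((0, 1), repeat=n):
        gamete1 = {locus: parent1[locus][k] for locus, k in zip(loci, picks1)}
        for picks2 in itertools.product((0, 1), repeat=n):
            gamete2 = {locus: parent2[locus][k] for locus, k in zip(loci, picks2)}
            geno = {locus: (gamete1[locus], gamete2[locus]) for locus in loci}
            key = canonical_genotype(geno, loci)
            out[key] = out.get(key, Fraction(0)) + half ** (2 * n)
    return GenotypeDistribution(out, loci)


def self_cross(parent: Genotype | str, loci: Sequence[str]) -> GenotypeDistribution:
    return cross(parent, parent, loci)


def condition_on(dist: GenotypeDistribution,
                 selector: Callable[[Genotype], bool]) -> GenotypeDistribution:
    """Renormalised distribution over genotypes kept by ``selector``.

    The selector receives the parsed genotype (locus -> allele pair).
    """
    kept: dict[str, Fraction] = {}
    for g, p in dist.items():
        geno = parse_genotype(g, dist.loci)
        if selector(geno) and p > 0:
            kept[g] = p
    total = sum(kept.values())
    if total == 0:
        raise ValueError("selector keeps no genotype with positive probability")
    return GenotypeDistribution({g: p / total for g, p in kept.items()}, dist.loci)


def carries_allele(locus: str, allele: str) -> Callable[[Genotype], bool]:
    """Phenotype selector: at least one copy of ``allele`` at ``locus``."""
    return lambda geno: allele in geno[locus]


def homozygous(locus: str, allele: str) -> Callable[[Genotype], bool]:
    return lambda geno: geno[locus] == (allele, allele)


def expected_counts(
    dist: GenotypeDistribution, n: int,
    class_collapse: Callable[[str], str] | None = None,
) -> dict[str, float]:
    """Expected class counts among ``n`` offspring (class probability x n)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    probs: dict[str, Fraction] = {}
    for g, p in dist.items():
        cls = class_collapse(g) if class_collapse else g
        probs[cls] = probs.get(cls, Fraction(0)) + p
    return {cls: float(p * n) for cls, p in probs.items()}


def class_probabilities(
    dist: GenotypeDistribution,
    class_collapse: Callable[[str], str] | None = None,
) -> dict[str, Fraction]:
    probs: dict[str, Fraction] = {}
    for g, p in dist.items():
        cls = class_collapse(g) if class_collapse else g
        probs[cls] = probs.get(cls, Fraction(0)) + p
    return probs


def goodness_of_fit(observed: Mapping[str, int],
                    probs: Mapping[str, Fraction | float]) -> GroupComparison:
    """Observed counts versus expected class probabilities.

    Reports the chi-square goodness-of-fit statistic; when any expected
    count falls below 5 an exact p-value is computed alongside (binomial
    for two classes, full multinomial enumeration for more when feasible).
    """
    classes = sorted(probs)
    if set(observed) - set(classes):
        raise ValueError(
            f"observed classes {sorted(set(observed) - set(classes))} missing from expectation"
        )
    obs = [int(observed.get(c, 0)) for c in classes]
    n = sum(obs)
    if n == 0:
        raise ValueError("no observed counts")
    p = [float(probs[c]) for c in classes]
    exp = [n * pi for pi in p]
    chi2, pval = sps.chisquare(obs, exp)
    exact = None
    if min(exp) < 5:
        warnings.warn("expected count < 5; chi-square approximation unreliable")
        exact = _exact_gof_p(obs, p)
    return GroupComparison(
        group_names=tuple(classes), group_sizes=tuple(obs),
        test="chi_square_gof", statistic=float(chi2), p_value=float(pval),
        group_means=tuple(exp), group_medians=(), exact_p_value=exact,
    )


def _exact_gof_p(obs: list[int], p: list[float]) -> float | None:
    n = sum(obs)
    if len(obs) == 2:
        return float(sps.binomtest(obs[0], n, p[0]).pvalue)
    if n > 200 or len(obs) > 4:
        return None
    # exact multinomial test: total probability of outcomes no more likely
    # than the observed one
    p_obs = sps.multinomial.pmf(obs, n, p)
    total = 0.0
    for combo in _compositions(n, len(obs)):
        q = sps.multinomial.pmf(combo, n, p)
        if q <= p_obs * (1 + 1e-12):
            total += q
    return float(min(total, 1.0))


def _compositions(n: int, k: int):
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, k - 1):
            yield (first, *rest)


def cross_from_config(config: Mapping) -> tuple[CrossSpec, GenotypeDistribution]:
    """Build a cross from a structured config (parsed YAML/JSON).

    Expected shape::

        loci: [T, B]
        parent1: "T/-;B/b"      # or {T: [T, "-"], B: [B, b]}
        parent2: "T/-;B/b"
    """
    loci = list(config["loci"])
    parents = []
    for key in ("parent1", "parent2"):
        val = config[key]
        parents.append(parse_genotype(val, loci) if isinstance(val, str)
                       else {k: tuple(v) for k, v in val.items()})
    spec = CrossSpec(loci, parents[0], parents[1])
    return spec, cross(spec.parent1, spec.parent2, loci)
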