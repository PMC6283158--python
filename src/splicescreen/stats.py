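"""Group-comparison statistics shared by the intron-feature analyses."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class GroupComparison:
    """Result of a two-group or goodness-of-fit comparison."""

    group_names: tuple[str, ...]
    group_sizes: tuple[int, ...]
    test: str  # two_sample_t | wilcoxon | chi_square_gof
    statistic: float
    p_value: float
    group_means: tuple[float, ...] = ()
    group_medians: tuple[float, ...] = ()
    exact_p_value: float | None = None


def compare_groups(values_a, values_b, test: str = "two_sample_t",
                   names: tuple[str, str] = ("a", "b")) -> GroupComparison:
    """Two-sided two-sample comparison.

    ``two_sample_t`` is Welch's t-test (unequal variances); ``wilcoxon``
    is the rank-sum (Mann-Whitney U) test as commonly labelled in figure
    legends.  Identical constant vectors under the t-test yield NaN with a
    warning rather than an error.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"two-sample tests need >= 2 values per group, got {len(a)} and {len(b)}")
    if test == "two_sample_t":
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            warnings.warn("both groups constant and identical; t-test undefined")
            stat, p = math.nan, math.nan
        else:
            stat, p = sps.ttest_ind(a, b, equal_var=False)
    elif test == "wilcoxon":
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(
        group_names=names,
        group_sizes=(len(a), len(b)),
        test=test,
        statistic=float(stat),
        p_value=float(p),
        group_means=(float(a.mean()), float(b.mean())),
        group_medians=(float(np.median(a)), float(np.median(b))),
    )


def chi_square_gof(observed, expected_probs) -> tuple[float, float]:
    """Chi-square goodness of fit of counts against class probabilities."""
    obs = np.asarray(observed, dtype=float)
    p = np.asarray(expected_probs, dtype=float)
    if obs.shape != p.shape:
        raise ValueError("observed counts and expected probabilities differ in length")
    if not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("expected probabilities must sum to 1")
    exp = p * obs.sum()
    chi2, pval = sps.chisquare(obs, exp)
    return float(chi2), float(pval)
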