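import itertools
import math

import numpy as np
import pytest

from splicescreen.annotation import Intron
from splicescreen.features import intron_features
from splicescreen.pwm import (PWM, build_pwm, extract_site_sequences,
                              gc_content, reverse_complement, score_site,
                              train_pwms_from_annotation)
from splicescreen.stats import compare_groups


@pytest.mark.parametrize("seq,expected", [
    ("ATGC", 0.5), ("GGCC", 1.0), ("ANGC", 2 / 3), ("atgc", 0.5),
])
def test_gc_content(seq, expected):
    assert gc_content(seq) == pytest.approx(expected)


@pytest.mark.parametrize("seq", ["", "NNN"])
def test_gc_content_rejects_empty(seq):
    with pytest.raises(ValueError):
        gc_content(seq)


def _random_sites(rng, n, width):
    return ["".join(rng.choice(list("ACGT"), size=width)) for _ in range(n)]


def test_pwm_cells_match_direct_formula():
    rng = np.random.default_rng(0)
    sites = _random_sites(rng, 50, 13)
    pwm = build_pwm(sites, "five_prime", pseudocount=0.5)
    for pos in range(13):
        for b_idx, base in enumerate("ACGT"):
            n_b = sum(s[pos] == base for s in sites)
            expected = math.log2((n_b + 0.5) / (len(sites) + 2) / 0.25)
            assert pwm.weights[pos, b_idx] == pytest.approx(expected)


def test_single_training_site_scores_maximum():
    site = "AAGGTAAGTTTTT"
    pwm = build_pwm([site], "five_prime")
    raw, norm = score_site(pwm, site)
    assert raw == pytest.approx(pwm.max_score)
    assert norm == pytest.approx(100.0)


def test_score_site_is_positionwise_sum():
    rng = np.random.default_rng(1)
    pwm = build_pwm(_random_sites(rng, 30, 13), "five_prime")
    seq = "ACGTACGTACGTA"
    raw, _ = score_site(pwm, seq)
    manual = sum(pwm.weights[i, "ACGT".index(b)] for i, b in enumerate(seq))
    assert raw == pytest.approx(manual)


def test_consensus_and_anticonsensus_normalised_bounds():
    rng = np.random.default_rng(2)
    pwm = build_pwm(_random_sites(rng, 40, 17), "three_prime")
    assert score_site(pwm, pwm.consensus())[1] == pytest.approx(100.0)
    assert score_site(pwm, pwm.anticonsensus())[1] == pytest.approx(0.0)


def test_single_base_improvement_monotone():
    rng = np.random.default_rng(3)
    pwm = build_pwm(_random_sites(rng, 40, 13), "five_prime")
    seq = list("ACGTACGTACGTA")
    raw0, _ = score_site(pwm, "".join(seq))
    for pos in range(13):
        improved = seq.copy()
        improved[pos] = pwm.consensus()[pos]
        raw1, _ = score_site(pwm, "".join(improved))
        assert raw1 >= raw0 - 1e-12


def test_ambiguous_base_scores_na():
    pwm = build_pwm(["AAGGTAAGTTTTT"], "five_prime")
    with pytest.warns(UserWarning, match="ambiguous"):
        raw, norm = score_site(pwm, "AAGGTAAGTTTTN")
    assert math.isnan(raw) and math.isnan(norm)


def _toy_genome_with_intron(intron_seq, strand, flank=30):
    """Contig carrying one intron; returns (genome, Intron)."""
    left = "C" * flank
    right = "A" * flank
    seq = left + intron_seq + right
    start, end = flank + 1, flank + len(intron_seq)
    if strand == "-":
        seq = reverse_complement(seq)
        length = len(seq)
        start, end = length - end + 1, length - start + 1
    return {"chr1": seq}, Intron("chr1", strand, start, end, {"T1"}, {"T1": 1})


def test_site_sequences_plus_strand_offsets():
    intron_seq = "GT" + "A" * 56 + "AG"
    genome, intron = _toy_genome_with_intron(intron_seq, "+")
    five, three = extract_site_sequences(intron, genome)
    assert len(five) == 13 and len(three) == 17
    assert five[3:5] == "GT" and three[12:14] == "AG"


def test_site_sequences_strand_invariant():
    """The same biological intron encoded on either strand yields identical
    site strings after reverse complementation."""
    intron_seq = "GTAAGT" + "C" * 50 + "TTTCAG"
    g_plus, i_plus = _toy_genome_with_intron(intron_seq, "+")
    g_minus, i_minus = _toy_genome_with_intron(intron_seq, "-")
    assert extract_site_sequences(i_plus, g_plus) == extract_site_sequences(i_minus, g_minus)


def test_non_canonical_atac_site_offsets():
    intron_seq = "AT" + "G" * 56 + "AC"
    genome, intron = _toy_genome_with_intron(intron_seq, "+")
    five, three = extract_site_sequences(intron, genome)
    assert five[3:5] == "AT" and three[12:14] == "AC"


def test_window_beyond_contig_errors():
    genome = {"chr1": "ACGT" * 10}
    intron = Intron("chr1", "+", 5, 38, {"T1"}, {"T1": 1})
    with pytest.raises(ValueError, match="contig"):
        extract_site_sequences(intron, genome)


def test_pwm_tsv_round_trip(tmp_path):
    rng = np.random.default_rng(4)
    pwm = build_pwm(_random_sites(rng, 20, 13), "five_prime")
    path = tmp_path / "pwm.tsv"
    pwm.to_tsv(path)
    loaded = PWM.from_tsv(path)
    assert loaded.side == "five_prime" and loaded.width == 13
    assert np.allclose(loaded.weights, pwm.weights, atol=1e-6)


def test_compare_groups_null_case():
    a = list(range(20))
    res = compare_groups(a, a, test="two_sample_t")
    assert abs(res.statistic) < 1e-9 and res.p_value > 0.9


def test_compare_groups_separated_samples():
    rng = np.random.default_rng(5)
    a = rng.normal(0, 1, 200)
    b = rng.normal(1, 1, 200)
    assert compare_groups(a, b, test="two_sample_t").p_value < 1e-3
    assert compare_groups(a, b, test="wilcoxon").p_value < 1e-3


def test_wilcoxon_matches_exact_enumeration():
    """Rank-sum p for tiny samples equals exhaustive permutation enumeration."""
    a = [1.2, 3.4, 2.2, 5.0, 0.7, 4.1, 2.9, 3.3]
    b = [2.0, 4.4, 5.1, 6.2, 3.8, 4.9, 5.5, 2.6]
    res = compare_groups(a, b, test="wilcoxon")
    pooled = a + b
    n = len(a)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    obs = sum(ranks[v] for v in a)
    count = total = 0
    for combo in itertools.combinations(pooled, n):
        total += 1
        stat = sum(ranks[v] for v in combo)
        if abs(stat - n * (len(pooled) + 1) / 2) >= abs(obs - n * (len(pooled) + 1) / 2) - 1e-12:
            count += 1
    assert res.p_value == pytest.approx(count / total, abs=1e-9)


def test_constant_identical_vectors_under_t_warns_na():
    with pytest.warns(UserWarning, match="constant"):
        res = compare_groups([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
    assert math.isnan(res.p_value)


def test_degraded_donors_lower_scores_in_retained_group():
    """Planting consensus-degraded donor sites in affected retained introns
    reproduces the qualitative weaker-5'-site signal for that group."""
    from splicescreen.simulate import SimConfig, simulate

    ds = simulate(SimConfig(seed=41, n_genes=250, frac_affected=0.3,
                            event_mix={"IR": 1.0}, degrade_affected_donors=True))
    pwm5, pwm3 = train_pwms_from_annotation(ds.introns, ds.genome)
    feats = intron_features(ds.introns, ds.genome, pwm5, pwm3)
    feats = feats.set_index(["start", "end"])
    degraded, normal = [], []
    degraded_keys = {g.designed_intron for g in ds.genes if g.degrade_donor}
    for (s, e), row in feats.iterrows():
        (degraded if (s, e) in degraded_keys else normal).append(row["score5_norm"])
    res = compare_groups(degraded, normal, test="two_sample_t")
    assert res.group_means[0] < res.group_means[1]
    assert res.p_value < 0.01
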