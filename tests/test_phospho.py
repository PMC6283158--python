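import math

import numpy as np
import pytest
from scipy.stats import norm

from splicescreen.phospho import (PhosphoError, PhosphoMod, PsmRecord,
                                  aggregate_sites, combine_test,
                                  compute_peptide_starts, notate_site,
                                  parse_modification, parse_site_notation,
                                  read_psm_table, site_tests)


def _psm(peptide, mods, masters, starts, control=10.0, treatment=10.0, rep=1):
    return PsmRecord(peptide, mods, masters, control, treatment, rep, starts)


class TestNotation:
    def test_single_site_single_master(self):
        psm = _psm("ILSSLSR", [PhosphoMod(("S",), 3, 100.0)],
                   ["AT1G01050.P2"], {"AT1G01050.P2": 22})
        assert notate_site(psm) == "Phospho:S:AT1G01050.P2:24"

    def test_multiple_master_proteins_chained_in_order(self):
        psm = _psm("DEPAEESDGDLGFGLFD", [PhosphoMod(("S",), 7, 100.0)],
                   ["AT1G01100.P2", "AT4G00810.c1", "AT5G47700.2"],
                   {"AT1G01100.P2": 96, "AT4G00810.c1": 97, "AT5G47700.2": 97})
        assert notate_site(psm) == \
            "Phospho:S:AT1G01100.P2:102:AT4G00810.c1:103:AT5G47700.2:103"

    def test_ambiguous_residue_class_dialect(self):
        psm = _psm("QSDTSPPPSPASK", [PhosphoMod(("T", "S"))],
                   ["AT1G01320.1"], {"AT1G01320.1": 145})
        assert notate_site(psm) == "S:AT1G01320.1:146/149/153/156|T:AT1G01320.1:148"

    def test_position_exceeding_peptide_errors(self):
        psm = _psm("ILSSLSR", [PhosphoMod(("S",), 30)], ["A"], {"A": 1})
        with pytest.raises(PhosphoError, match="exceeds"):
            notate_site(psm)

    def test_residue_mismatch_errors(self):
        psm = _psm("ILSSLSR", [PhosphoMod(("T",), 3)], ["A"], {"A": 1})
        with pytest.raises(PhosphoError, match="does not match"):
            notate_site(psm)

    def test_missing_peptide_start_errors(self):
        psm = _psm("ILSSLSR", [PhosphoMod(("S",), 3)], ["A", "B"], {"A": 1})
        with pytest.raises(PhosphoError, match="peptide start"):
            notate_site(psm)

    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_random_psms(self, seed):
        rng = np.random.default_rng(seed)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(40):
            pep = "".join(rng.choice(aa, size=int(rng.integers(7, 20))))
            sty = [i + 1 for i, a in enumerate(pep) if a in "STY"]
            if not sty:
                continue
            masters = [f"AT{int(rng.integers(1, 5))}G{int(rng.integers(10000, 99999))}.1"]
            starts = {masters[0]: int(rng.integers(1, 500))}
            if rng.random() < 0.5:
                pos = int(sty[rng.integers(len(sty))])
                mods = [PhosphoMod((pep[pos - 1],), pos, 100.0)]
            else:
                residues = tuple(sorted({pep[i - 1] for i in sty}))
                mods = [PhosphoMod(residues)]
            psm = _psm(pep, mods, masters, starts)
            notation = notate_site(psm)
            parsed = parse_site_notation(notation)
            for site in parsed:
                residue = site["residue"]
                for acc, positions in site["positions"].items():
                    for p in positions:
                        assert pep[p - starts[acc]] == residue

    def test_same_protein_site_from_different_peptides_collides_on_purpose(self):
        # residue S at protein position 25 reached via two different peptide
        # offsets is one biological site -> one notation
        a = _psm("ILSSLSR", [PhosphoMod(("S",), 4)], ["A"], {"A": 22})
        b = _psm("LSSLSRX", [PhosphoMod(("S",), 3)], ["A"], {"A": 23})
        assert notate_site(a) == notate_site(b)

    def test_notation_distinct_for_distinct_sites(self):
        seen = set()
        for pos, start in [(3, 22), (4, 22), (6, 22), (3, 40)]:
            psm = _psm("ILSSLSR", [PhosphoMod(("S",), pos)], ["A"], {"A": start})
            notation = notate_site(psm)
            assert notation not in seen
            seen.add(notation)


def test_parse_modification_dialects():
    assert parse_modification("Phospho [S3(100)]") == [PhosphoMod(("S",), 3, 100.0)]
    assert parse_modification("2xPhospho [S3(99.1); T5(80)]") == [
        PhosphoMod(("S",), 3, 99.1), PhosphoMod(("T",), 5, 80.0)]
    assert parse_modification("Phospho [T/S]") == [PhosphoMod(("T", "S"))]
    with pytest.raises(PhosphoError):
        parse_modification("Oxidation [M1]")


def test_compute_peptide_starts_from_sequences():
    proteins = {"P1": "MKAAAILSSLSRGG"}
    assert compute_peptide_starts("ILSSLSR", ["P1"], proteins) == {"P1": 6}
    with pytest.raises(PhosphoError, match="not found"):
        compute_peptide_starts("WWWWWWW", ["P1"], proteins)


class TestAggregation:
    def _three_site_psms(self):
        psms = []
        # three sites with replicate-1 log ratios 0, 1, 2
        for i, ratio in enumerate([1.0, 2.0, 4.0]):
            pep = ["SAAAAAK", "SCCCCCK", "SDDDDDK"][i]
            psms.append(_psm(pep, [PhosphoMod(("S",), 1)], [f"P{i}"], {f"P{i}": 1},
                             control=10.0, treatment=10.0 * ratio))
        return psms

    def test_sums_and_log_ratio_additivity(self):
        base = _psm("SAAAAAK", [PhosphoMod(("S",), 1)], ["P"], {"P": 1},
                    control=10.0, treatment=20.0)
        extra = _psm("SAAAAAK", [PhosphoMod(("S",), 1)], ["P"], {"P": 1},
                     control=30.0, treatment=60.0)
        (stat,) = [s for s in aggregate_sites([base, extra])]
        assert (stat.sum_control, stat.sum_treatment) == (40.0, 80.0)
        assert stat.log_ratio == pytest.approx(1.0)

    def test_z_standardisation_hand_computed(self):
        stats = aggregate_sites(self._three_site_psms())
        zs = sorted(s.z for s in stats)
        # log ratios {0,1,2}: mean 1, sample sd 1 -> z = {-1, 0, 1}
        assert zs == pytest.approx([-1.0, 0.0, 1.0])

    def test_within_replicate_z_moments(self):
        rng = np.random.default_rng(11)
        psms = []
        for i in range(50):
            pep = "S" + "".join(rng.choice(list("ACDEFGHILMNPQVWY"), size=5)) + "K"
            psms.append(_psm(pep, [PhosphoMod(("S",), 1)], [f"P{i}"], {f"P{i}": 1},
                             control=float(rng.lognormal(10, 1)),
                             treatment=float(rng.lognormal(10, 1))))
        zs = np.array([s.z for s in aggregate_sites(psms)])
        assert abs(zs.mean()) < 1e-9
        assert zs.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_permutation_invariance(self):
        psms = self._three_site_psms() * 2
        fwd = {(s.site, s.replicate): (s.sum_control, s.sum_treatment)
               for s in aggregate_sites(psms)}
        rev = {(s.site, s.replicate): (s.sum_control, s.sum_treatment)
               for s in aggregate_sites(psms[::-1])}
        assert fwd == rev

    def test_zero_channel_excluded_with_warning(self):
        psms = self._three_site_psms()
        psms.append(_psm("SEEEEEK", [PhosphoMod(("S",), 1)], ["PZ"], {"PZ": 1},
                         control=0.0, treatment=5.0))
        with pytest.warns(UserWarning, match="zero channel"):
            stats = aggregate_sites(psms)
        assert all(s.site != "Phospho:S:PZ:1" for s in stats)

    def test_detection_count_across_replicates(self):
        psms = [_psm("SAAAAAK", [PhosphoMod(("S",), 1)], ["P"], {"P": 1}, rep=r)
                for r in (1, 3)]
        stats = aggregate_sites(psms)
        assert sorted(s.replicate for s in stats) == [1, 3]


class TestCombineTest:
    def _stats(self, zs):
        from splicescreen.phospho import SiteReplicateStat

        return [SiteReplicateStat("X", r + 1, 1.0, 1.0, z, z)
                for r, z in enumerate(zs)]

    def test_null_zs(self):
        res = combine_test(self._stats([0.0, 0.0]))
        assert res.combined_z == 0.0 and res.p_value == pytest.approx(1.0)

    def test_three_unit_zs_closed_form(self):
        res = combine_test(self._stats([1.0, 1.0, 1.0]))
        assert res.combined_z == pytest.approx(math.sqrt(3))
        assert res.p_value == pytest.approx(2 * norm.sf(math.sqrt(3)), rel=1e-9)
        assert res.p_value == pytest.approx(0.0833, abs=2e-4)

    def test_strong_pair_closed_form(self):
        res = combine_test(self._stats([2.5, 2.5]))
        assert res.combined_z == pytest.approx(2.5 * math.sqrt(2))
        assert res.p_value == pytest.approx(4.1e-4, abs=5e-5)

    def test_single_replicate_not_tested(self):
        res = combine_test(self._stats([2.5]))
        assert res.k == 1 and math.isnan(res.p_value)

    def test_one_sample_t_alternative(self):
        res = combine_test(self._stats([1.0, 1.2, 0.9]), method="one_sample_t")
        assert res.p_value < 0.05

    def test_per_replicate_flags(self):
        res = combine_test(self._stats([2.5, 0.3]), z_cutoff=1.96)
        assert res.per_replicate_flags == {1: True, 2: False}


def test_site_tests_planted_effects_detected(sim_small):
    results = site_tests(sim_small.psms)
    truth = sim_small.truth_sites.set_index("site")
    assert set(r.site for r in results) == set(truth.index)
    detected = {r.site: r for r in results
                if not math.isnan(r.p_value) and r.p_value < 0.05}
    affected = truth.index[truth.affected]
    hits = [s for s in affected if s in detected]
    assert len(hits) / max(len(affected), 1) >= 0.7
    for s in hits:
        assert detected[s].direction == truth.loc[s, "direction"]


def test_read_psm_table_round_trip(sim_small, tmp_path):
    psms = read_psm_table(sim_small.paths["psm"])
    assert len(psms) == len(sim_small.psms)
    orig = sorted(notate_site(p) for p in sim_small.psms)
    loaded = sorted(notate_site(p) for p in psms)
    assert orig == loaded
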