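import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import quant_from_dataset
from splicescreen.events import SpliceEvent
from splicescreen.psi import (QuantTable, compute_psi, delta_psi_test,
                              delta_psi_test_from_table, isoform_fractions,
                              psi_table)


def _event(inclusion, exclusion, eid="G;IR;chr1:101-200:+"):
    return SpliceEvent(eid, "G", "IR", "chr1", "+", ((101, 200),), None,
                       frozenset(inclusion), frozenset(exclusion), "variable")


def _quant(tpms: dict[str, dict[str, float]]):
    samples = sorted(tpms)
    design = {}
    for s in samples:
        cond, rep = s.rsplit("_", 1)
        design[s] = (cond, int(rep))
    return QuantTable(samples, design, pd.DataFrame(tpms).fillna(0.0))


@pytest.mark.parametrize("inc,exc,expected", [
    ({"I1": 10.0}, {"E1": 10.0}, 0.5),
    ({"I1": 7.0}, {"E1": 0.0}, 1.0),
    ({"I1": 2.0, "I2": 2.0}, {"E1": 4.0, "E2": 8.0}, 0.25),
])
def test_compute_psi_values(inc, exc, expected):
    quant = _quant({"control_1": {**inc, **exc}})
    ev = _event(inc, exc)
    assert compute_psi(ev, quant, "control_1") == pytest.approx(expected)


def test_compute_psi_undefined_below_floor():
    quant = _quant({"control_1": {"I1": 0.0, "E1": 0.0}})
    assert math.isnan(compute_psi(_event({"I1"}, {"E1"}), quant, "control_1"))


def test_compute_psi_unknown_sample_errors():
    quant = _quant({"control_1": {"I1": 1.0, "E1": 1.0}})
    with pytest.raises(KeyError):
        compute_psi(_event({"I1"}, {"E1"}), quant, "nope")


def test_missing_transcript_treated_as_zero_with_warning():
    quant = _quant({"control_1": {"I1": 5.0}})
    with pytest.warns(UserWarning, match="absent"):
        assert compute_psi(_event({"I1"}, {"GHOST"}), quant, "control_1") == 1.0


@pytest.mark.parametrize("tpms,expected", [
    ({"unspliced": 50.0, "GTAG": 30.0, "ATAC": 20.0}, {"unspliced": 0.5, "GTAG": 0.3, "ATAC": 0.2}),
    ({"only": 8.0}, {"only": 1.0}),
])
def test_isoform_fractions(tpms, expected):
    quant = _quant({"control_1": tpms})
    fr = isoform_fractions("G", list(tpms), quant, "control_1")
    assert fr == pytest.approx(expected)


def test_isoform_fractions_all_zero_is_na():
    quant = _quant({"control_1": {"a": 0.0, "b": 0.0}})
    fr = isoform_fractions("G", ["a", "b"], quant, "control_1")
    assert all(math.isnan(v) for v in fr.values())


@settings(max_examples=30, deadline=None, derandomize=True)
@given(scale=st.floats(min_value=1e-3, max_value=1e3),
       inc=st.floats(min_value=0.1, max_value=100),
       exc=st.floats(min_value=0.1, max_value=100))
def test_psi_invariant_to_per_sample_scaling(scale, inc, exc):
    ev = _event({"I1"}, {"E1"})
    base = _quant({"control_1": {"I1": inc, "E1": exc}})
    scaled = _quant({"control_1": {"I1": inc * scale, "E1": exc * scale}})
    a = compute_psi(ev, base, "control_1", expression_floor=0.0)
    b = compute_psi(ev, scaled, "control_1", expression_floor=0.0)
    assert a == pytest.approx(b, rel=1e-9)


def _sim_table(rng, n_events=400, n_affected=0, sigma=0.05, reps=3):
    rows = []
    truth = []
    for i in range(n_events):
        affected = i < n_affected
        c = rng.uniform(0.2, 0.55)
        mdelta = 0.3 if affected else 0.0
        row = {"event_id": f"E{i}", "type": "IR", "gene_id": f"G{i}", "first_intron": False}
        tpm = rng.lognormal(4, 1)
        for cond, true in (("control", c), ("mutant", c + mdelta)):
            for r in range(1, reps + 1):
                x = math.log(true / (1 - true)) + rng.normal(0, sigma)
                row[f"psi_{cond}_{r}"] = 1 / (1 + math.exp(-x))
                row[f"tpm_{cond}_{r}"] = tpm
        rows.append(row)
        truth.append(affected)
    design = {f"{cond}_{r}": (cond, r) for cond in ("control", "mutant")
              for r in range(1, reps + 1)}
    return pd.DataFrame(rows), design, truth


def test_identical_psi_never_significant():
    rng = np.random.default_rng(0)
    table, design, _ = _sim_table(rng, n_events=50, sigma=0.0)
    records = delta_psi_test_from_table(table, design)
    assert all(r.delta_psi == 0 for r in records)
    assert not any(r.significant for r in records)


def test_label_swap_negates_dpsi_and_keeps_p():
    rng = np.random.default_rng(1)
    table, design, _ = _sim_table(rng, n_events=200, n_affected=20)
    fwd = delta_psi_test_from_table(table, design)
    swapped = {s: ("mutant" if c == "control" else "control", r)
               for s, (c, r) in design.items()}
    rev = delta_psi_test_from_table(table, swapped)
    for a, b in zip(fwd, rev):
        assert a.delta_psi == pytest.approx(-b.delta_psi, abs=1e-12)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)


def test_planted_effect_recovered_and_na_excluded():
    rng = np.random.default_rng(2)
    table, design, truth = _sim_table(rng, n_events=500, n_affected=50)
    table.loc[0, "psi_control_1"] = math.nan  # knock one event out of testing
    records = delta_psi_test_from_table(table, design)
    assert math.isnan(records[0].p_value) and not records[0].significant
    sig = [r.significant for r in records]
    affected = [t and not math.isnan(r.p_value) for t, r in zip(truth, records)]
    sens = sum(s and a for s, a in zip(sig, affected)) / sum(affected)
    assert sens >= 0.9
    false = sum(s and not a for s, a in zip(sig, affected))
    assert false / max(sum(sig), 1) <= 0.1


def test_too_few_replicates_error():
    rng = np.random.default_rng(3)
    table, design, _ = _sim_table(rng, n_events=10, reps=2)
    design = {s: d for s, d in design.items() if s != "control_2"}
    with pytest.raises(ValueError, match="replicates"):
        delta_psi_test_from_table(table[[c for c in table.columns
                                         if "control_2" not in c]], design)


def test_end_to_end_psi_against_truth(sim_small):
    """Noisy sample PSI stays close to the generating truth per event."""
    quant = quant_from_dataset(sim_small)
    table = psi_table(sim_small.events, quant)
    truth = sim_small.truth_events.set_index("event_id")
    merged = table.set_index("event_id").join(truth[["psi_control"]])
    resid = (merged["psi_control_1"] - merged["psi_control"]).dropna()
    assert resid.abs().mean() < 0.05
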