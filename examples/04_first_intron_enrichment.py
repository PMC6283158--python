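"""Test whether differentially retained introns are enriched for first introns.

Two parts: (1) a reported screen count table — 585 of 1402 differentially
retained introns are first introns (41.7%) against a 27.2% annotation-wide
expectation — tested by chi-square goodness of fit; (2) the same analysis
end-to-end on synthetic data with a planted first-intron bias.
"""

from splicescreen import (SimConfig, delta_psi_test, first_intron_enrichment,
                          partition_ir, simulate)
from splicescreen.psi import QuantTable

res = first_intron_enrichment((585, 817), expected_first_fraction=0.272)
print("reported count table:")
print(f"  observed first-intron share: {100 * 585 / 1402:.1f}%  (expected 27.2%)")
print(f"  chi-square = {res.chi_square:.1f} (1 df), p = {res.p_value:.3g}")

ds = simulate(SimConfig(seed=4, n_genes=1000, event_mix={"IR": 1.0},
                        ir_introns_range=(2, 3), frac_affected=0.2,
                        first_intron_affected_prob=0.8))
design = {row["sample"]: (row["condition"], int(row["replicate"]))
          for _, row in ds.design.iterrows()}
quant = QuantTable(list(ds.design["sample"]), design, ds.tpm)
records = delta_psi_test(ds.events, quant)
by_id = {e.event_id: e for e in ds.events}
sig_ir = [by_id[r.event_id] for r in records if r.significant]

part = partition_ir(sig_ir, ds.events)
enr = first_intron_enrichment(part)
print("\nsynthetic benchmark (first-intron bias planted in affected events):")
print(f"  regulated IR events: {len(part.first) + len(part.remaining)} "
      f"({len(part.first)} first / {len(part.remaining)} remaining)")
print(f"  annotation expectation: {100 * part.annotation_first_fraction:.1f}% first")
print(f"  chi-square = {enr.chi_square:.1f}, p = {enr.p_value:.3g}")
# A small p-value says regulated retention hits first introns more often
# than the annotation's background share would predict.
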