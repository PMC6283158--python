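"""Remove splicing events whose splice sites carry background mutations.

On mutagenised material, a variant inside a splice-site window (last 3
exonic + first 10 intronic bases at the donor; last 14 intronic + first 3
exonic at the acceptor) can itself change splicing, so such events are
removed before interpreting differential results.
"""

from splicescreen import SimConfig, filter_events, simulate
from splicescreen.mask import Variant

ds = simulate(SimConfig(seed=2, n_genes=300, n_variants_in_window=12,
                        n_variants_out_window=40, n_indels_in_window=2))
variants = [Variant(v.chrom, v.pos, v.ref, v.alt) for v in ds.variants]

kept, removed = filter_events(ds.events, variants)
removed_ids = {r.event_id for r in removed}
flagged = set(ds.truth_variants.event_id[ds.truth_variants.masked])

print(f"events:            {len(ds.events)}")
print(f"variants:          {len(variants)} "
      f"({sum(v.is_ems_transition for v in variants)} EMS-type G/A->C/T transitions)")
print(f"events removed:    {len(removed_ids)} (planted in-window: {len(flagged)})")
print(f"events kept:       {len(kept)}")
rec = removed[0]
print(f"example removal:   {rec.event_id}")
print(f"  {rec.variant.kind} {rec.variant.chrom}:{rec.variant.pos} "
      f"{rec.variant.ref}>{rec.variant.alt} overlaps the {rec.side} window "
      f"[{rec.window.start}, {rec.window.end}]")
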