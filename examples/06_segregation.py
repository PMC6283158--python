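"""Mendelian expectations for a double-mutant viability cross.

A plant heterozygous for a second kinase allele (B/b), homozygous for the
first (a/a) and carrying a hemizygous reporter transgene (T/-) is selfed.
Progeny are prescreened for the reporter phenotype; among the selected
plants the second locus should still segregate 1:2:1, so a deficit of b/b
progeny indicates the double homozygote is not viable.
"""

from splicescreen import condition_on, expected_counts, goodness_of_fit, self_cross
from splicescreen.genetics import class_probabilities

loci = ["T", "A", "B"]
dist = self_cross("T/-;A/a;B/b", loci)
selected = condition_on(dist, lambda g: "T" in g["T"] and g["A"] == ("a", "a"))
marginal = selected.marginal("B")

print("B-locus distribution among reporter-selected progeny:")
for geno, p in sorted(marginal.items()):
    print(f"  {geno}: {p} ({float(p):.0%})")

counts = expected_counts(marginal, 54)
print(f"\nexpected among 54 genotyped plants: "
      f"b/b = {counts['b/b']:g}, B/b = {counts['B/b']:g}, B/B = {counts['B/B']:g}")

observed = {"b/b": 0, "B/b": 5, "B/B": 49}
res = goodness_of_fit(observed, class_probabilities(marginal))
print(f"\nobserved 0 b/b and 5 B/b among 54:")
print(f"  chi-square = {res.statistic:.1f}, p = {res.p_value:.3g}")
# The strong deviation from 13.5 : 27 : 13.5 indicates the doubly
# homozygous class is missing (inviable) and the b allele is under-
# transmitted in the a/a background.
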