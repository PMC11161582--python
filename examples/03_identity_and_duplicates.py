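"""Individual identification: duplicates, psex and identity indices.

Finds re-sampled animals by exhaustive genotype matching, quantifies the
chance of such matches arising randomly (psex), and reports how many loci
a forensic panel needs for probability of identity < 0.01.
"""

import pangotrace as pt

model, table = pt.survey_scenario(seed=42)
part = pt.PopulationMap.from_metadata(table)

matches = pt.find_matches(table, max_mismatch_loci=0, min_shared_loci=10)
print(f"{len(matches)} identical genotype pairs among "
      f"{table.n_individuals} samples")

aft = pt.allele_counts(table, part).pooled()
m = matches[0]
p = pt.pgen(pt.genotype_of(table, m.id1), aft)
print(f"example pair {m.id1} ~ {m.id2}: pgen = {p:.3g}, "
      f"psex = {pt.psex(p, table.n_individuals):.3g} "
      "(chance of a random repeat: effectively zero -> same animal)")

pi = pt.probability_of_identity(aft)
print(pi.per_locus[["locus", "PI", "uPI", "PIsibs"]].head(5).round(4))
print(f"cumulative uPI over all loci: {pi.cumulative['uPI']:.3g}")
k = pt.min_loci_for_pi(pi.per_locus["PI"], threshold=0.01)
print(f"loci needed for PI < 0.01: {k} "
      "(a small subset of the panel already individualises)")
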