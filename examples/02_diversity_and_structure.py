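"""Reference-population diversity, differentiation and isolation by distance.

Prints the Table-1-style summary (Na, Ho, He, uHe, F_IS, allelic richness,
private alleles), the pairwise Weir-Cockerham F_ST range, and the
individual-level Mantel test of genetic vs geographic distance.
"""

import numpy as np

import pangotrace as pt

model, table = pt.survey_scenario(seed=42)
part = pt.PopulationMap.from_metadata(table)

summary = pt.diversity(table, part, fis_randomizations=199, seed=1)
print(summary.per_population.round(3))
# Positive F_IS with low F_ST is the Wahlund-like signature the generator
# builds in: pooled differentiated breeding units, not true inbreeding.

fst = pt.pairwise_fst(table, part)
off = fst.theta.to_numpy()[np.triu_indices(len(part.populations), k=1)]
print(f"\npairwise F_ST: {off.min():.3f} .. {off.max():.3f}")

refs = table.subset([i for i in table.individuals
                     if table.metadata.loc[i, "cls"] == "reference"])
gd = pt.edwards_distance(refs)
geo = pt.geographic_distance_matrix(refs.metadata[["lon", "lat"]].to_numpy())
ibd = pt.mantel_ibd(gd, geo, n_permutations=999, seed=2)
print(f"Mantel IBD: r = {ibd.r:.3f}, p = {ibd.p:.3g} "
      "(positive r: nearby animals are genetically closer)")
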