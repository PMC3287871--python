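"""Simulate a multi-family sequencing study and write it to disk.

Generates 3 extended families by gene dropping: rare variants grouped into
genes (founder MAF below 1%), a common-marker panel for IBS/PCA, and
replicate quantitative traits with a polygenic familial component plus one
causal collapsed-gene effect.
"""

import numpy as np

from famburden import SimConfig, simulate_study, write_study

cfg = SimConfig(
    n_families=5,
    offspring_range=(5, 7),
    n_genes=20,
    n_common_markers=1000,
    causal_genes={"gene0005": 0.8},   # +0.8 trait units for rare carriers
    heritability_polygenic=0.6,
    sigma2_e=0.4,
    n_replicates=5,
    seed=43,
)
study = simulate_study(cfg)

ped = study.pedigree
geno = study.genotypes
print(f"pedigree: {len(ped)} subjects in {len(ped.family_ids)} families "
      f"({len(ped.founders())} founders)")
print(f"genotypes: {geno.n_variants} variants "
      f"({int((geno.maf < 0.01).sum())} rare at MAF < 0.01)")
print(f"traits: {study.n_replicates} replicates, "
      f"per-replicate variance ~ {study.traits.var(axis=1).mean():.2f} "
      "(beta^2 var(X) + sigma2_g + sigma2_e)")

carriers = int(np.sum(
    study.genotypes.dosages[:, (geno.variant_meta['gene'] == 'gene0005').to_numpy()
                            & (geno.maf < 0.01)].max(axis=1) > 0))
print(f"causal gene gene0005: {carriers} rare-allele carriers")

write_study(study, "scratch/example_study")
print("study written to scratch/example_study/ "
      "(pedigree.fam, genotypes.tsv, variants.tsv, truth.tsv, traits/)")
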