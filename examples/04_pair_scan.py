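"""Two-dimensional genome scan for epistasis.

Plants a pure product-term interaction (15% of variance) between markers on
chromosomes II and V — invisible to single-marker scans under symmetric
allele coding — and shows that the marker-pair interaction LOD localizes it.
"""

import numpy as np

import riailmap as rm

geno = rm.simulate_riail_panel(296, seed=4)
mk = geno.markers
i = int(mk.index[mk["chrom"] == "II"][15])
j = int(mk.index[mk["chrom"] == "V"][25])
arch = rm.ArchitectureSpec(epistatic_pairs=[(i, j, 0.15)], trait_loadings=np.array([1.0]))
trait = rm.simulate_phenotypes(geno, arch, seed=5).iloc[:, 0]

marginal = rm.lod_scan(trait, geno)
print(f"planted pair: {mk.iloc[i]['marker']} x {mk.iloc[j]['marker']}")
print(f"marginal LOD at the two planted markers: "
      f"{marginal.lod[i]:.2f}, {marginal.lod[j]:.2f}  (flat: no single-marker signal)")

res = rm.pair_scan(trait, geno, grid_step_cM=15.0, n_perm=1000, seed=6)
pi, pj = res.peak_pair()
print(f"interaction scan peak: {mk.iloc[pi]['marker']} x {mk.iloc[pj]['marker']}, "
      f"LOD_interaction = {res.lod_interaction.max():.2f} "
      f"(5% GWER threshold {res.threshold:.2f})")
print("(LOD_interaction = LOD of the full two-locus model minus the additive "
      "model; significance from 1000 phenotype permutations)")
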