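"""Simulate a backcross, scan the genome, and test significance.

This walks the basic mapping loop: breed a reciprocal backcross population
on the default 140-marker framework map, plant a single additive QTL on the
disease liability, run a Haley-Knott genome scan, and compare the peak to a
permutation-derived genome-wide threshold.
"""

import numpy as np

from poqtl.genmap import default_rat_map
from poqtl.genoprob import calc_genoprob
from poqtl.scan import bootstrap_localize, permute_threshold, scan_hk
from poqtl.simulate import QTLSpec, breed_backcross, combine, \
    simulate_phenotypes

gmap = default_rat_map()
print(f"map: {len(gmap.chromosomes)} chromosomes, {gmap.n_markers} markers")

# Both reciprocal crosses of the DA-background population, 110 rats each.
pop = combine([breed_backcross("DAxF1", 110, gmap, seed=1),
               breed_backcross("F1xDA", 110, gmap, seed=2)])

# One additive QTL on chromosome 4 (PVG allele increases disease liability
# by 0.8 residual SD per copy), then EAE-like clinical phenotypes.
qtl = QTLSpec(chrom="4", pos_mb=144.0, mode="additive", effect=0.8,
              risk_strain="P")
phenos = simulate_phenotypes(pop, [qtl], seed=3)
print(f"incidence: {phenos['INC'].mean():.2f}")

# Conditional genotype probabilities on a 2 Mb pseudomarker grid, then a
# Haley-Knott scan of onset day.
probs = calc_genoprob(pop.genotype_codes(), gmap, step_mb=2.0)
res = scan_hk(probs, phenos["ONS"].to_numpy(float), pheno_name="ONS")
peak = res.max()
print(f"peak LOD {peak['lod']:.2f} at chr{peak['chrom']} "
      f"{peak['pos_mb']:.1f} Mb (true QTL: chr4 144.0 Mb)")

# Genome-wide significance by phenotype permutation.
thr = permute_threshold(probs, phenos["ONS"].to_numpy(float),
                        n_perm=500, alpha=0.05, seed=4)
print(f"genome-wide 5% threshold: {thr.value:.2f} "
      f"-> {'significant' if peak['lod'] >= thr.value else 'not significant'}")

# Localize the peak by case bootstrap.
loc = bootstrap_localize(probs, phenos["ONS"].to_numpy(float),
                         chrom=str(peak["chrom"]), n_boot=300, seed=5)
lo, hi = loc.interval
print(f"bootstrap 95% localization: {lo:.0f}-{hi:.0f} Mb "
      f"({hi - lo:.0f} Mb wide)")

assert peak["chrom"] == "4" and np.isfinite(peak["lod"])
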