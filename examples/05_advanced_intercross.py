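"""Advanced intercross mapping resolution and detection power.

Ten generations of random intercrossing accumulate recombinations, which
decouples nearby markers and sharpens QTL peaks relative to a backcross.
An intercross segregates three genotype classes, so instead of the
two-state backcross scan this compares marker-dosage regressions directly;
it then tests the origin-by-QTL interaction (the intercross analogue of
the reciprocal-cross comparison) and closes with a power curve.
"""

import numpy as np

from poqtl.genmap import make_map
from poqtl.poo import interaction_test
from poqtl.simulate import (QTLSpec, breed_ail, breed_backcross,
                            effect_from_varexp, power_by_simulation,
                            simulate_phenotypes)

# One 100 cM chromosome with 21 markers for a sharp comparison.
gmap = make_map({"1": 100.0}, {"1": 21})
qtl = QTLSpec("1", 90.9, "additive", 0.8, "P")


def lod_curve(dosage, y):
    """Per-marker regression LOD of phenotype on allele dosage."""
    n = len(y)
    yc = y - y.mean()
    rss0 = yc @ yc
    lods = np.empty(dosage.shape[1])
    for j in range(dosage.shape[1]):
        x = dosage[:, j] - dosage[:, j].mean()
        ssx = x @ x
        rss1 = rss0 - (x @ yc) ** 2 / ssx if ssx > 0 else rss0
        lods[j] = (n / 2) * np.log10(rss0 / rss1)
    return lods


def support_interval(pop, seed):
    """Peak LOD and the width of the 1.5-LOD support interval."""
    phenos = simulate_phenotypes(pop, [qtl], seed=seed)
    y = phenos["MAX"].to_numpy(float)
    lods = lod_curve(pop.dosage("P").astype(float), y)
    mb = gmap.positions_mb("1")
    inside = mb[lods >= lods.max() - 1.5]
    return lods.max(), inside.max() - inside.min()


bc = breed_backcross("F1xDA", 400, gmap, seed=31)
ail = breed_ail(20, generations=10, n_final=400, gmap=gmap, seed=32)

# map expansion: adjacent-marker genotype switches per gamete
def switch_rate(pop):
    return float(np.mean(np.diff(pop.maternal.astype(int), axis=1) != 0))

print(f"adjacent-marker switch rate: backcross {switch_rate(bc):.3f}, "
      f"AIL G10 {switch_rate(ail):.3f}")

lod_bc, w_bc = support_interval(bc, seed=33)
lod_ail, w_ail = support_interval(ail, seed=34)
print(f"backcross:  peak LOD {lod_bc:5.1f}, 1.5-LOD interval {w_bc:5.0f} Mb")
print(f"AIL (G10):  peak LOD {lod_ail:5.1f}, 1.5-LOD interval {w_ail:5.0f} Mb")

# In an AIL each rat carries a recorded family origin; origin-by-QTL
# interactions play the role the reciprocal crosses play in a backcross.
phenos = simulate_phenotypes(ail, [qtl], seed=35)
pos = [("1", 90.9)]
table = interaction_test(ail, phenos, pos, pos, covariate="origin",
                         n_imp=32, seed=36)
print("\norigin x QTL interaction p-values (additive QTL, expect large):")
print(table.to_string(float_format=lambda v: f"{v:.3f}"))

# Detection power by simulation: effect size from variance explained.
print("\nbackcross power at genome-wide LOD 2.7 (n = 200):")
for varexp in (0.02, 0.05, 0.10):
    eff = effect_from_varexp(varexp)
    pct, se = power_by_simulation(eff, 200, n_sim=200, threshold_lod=2.7,
                                  seed=37)
    print(f"  variance explained {100 * varexp:4.0f}% "
          f"(effect {eff:.2f} SD): power {pct:5.1f}% +/- {se:.1f}%")

assert switch_rate(ail) > switch_rate(bc)
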