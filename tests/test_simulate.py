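"""Simulation layer: maps, meiosis, cross designs, phenotype model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from poqtl.genmap import GeneticMap, default_rat_map, haldane, make_grid, make_map
from poqtl.simulate import (D, P, PhenotypeModelParams, QTLSpec, breed_ail,
                            breed_backcross, combine, cross_design,
                            effect_from_varexp, simulate_phenotypes,
                            substream)

# ---------------------------------------------------------------------------
# map and Haldane function


def test_haldane_closed_form_values():
    # r = (1 - exp(-2d/100)) / 2
    assert haldane(0.0) == 0.0
    assert np.isclose(haldane(20.0), 0.5 * (1 - np.exp(-0.4)), atol=1e-15)
    assert np.isclose(haldane(20.0), 0.16484, atol=5e-6)
    assert haldane(1e6) == pytest.approx(0.5)
    # monotone increasing and bounded by 0.5
    d = np.linspace(0, 300, 50)
    r = haldane(d)
    assert np.all(np.diff(r) > 0) and np.all(r < 0.5)


def test_haldane_rejects_negative_distance():
    with pytest.raises(ValueError):
        haldane(-1.0)


def test_default_map_has_140_markers_on_20_autosomes():
    gmap = default_rat_map()
    assert gmap.n_markers == 140
    assert len(gmap.chromosomes) == 20
    for chrom in gmap.chromosomes:
        cm = gmap.positions_cm(chrom)
        assert np.allclose(np.diff(cm), 20.0)   # 20 cM spacing


def test_map_validation_errors():
    t = pd.DataFrame({"marker": ["a", "a"], "chrom": ["1", "1"],
                      "pos_cm": [0.0, 10.0], "pos_mb": [0.0, 18.18]})
    with pytest.raises(ValueError, match="duplicate"):
        GeneticMap(t)
    t2 = pd.DataFrame({"marker": ["a", "b"], "chrom": ["1", "1"],
                       "pos_cm": [10.0, 10.0], "pos_mb": [18.18, 18.18]})
    with pytest.raises(ValueError, match="increasing"):
        GeneticMap(t2)


def test_grid_markers_only_and_step():
    gmap = default_rat_map()
    grids = make_grid(gmap, step_mb=0)
    assert sum(g.n for g in grids.values()) == 140
    grids1 = make_grid(gmap, step_mb=10.0)
    for chrom, g in grids1.items():
        # markers all retained, positions strictly increasing
        assert set(gmap.positions_mb(chrom)) <= set(g.pos_mb)
        assert np.all(np.diff(g.pos_mb) > 0)
        assert np.all(np.diff(g.pos_mb) <= 10.0 + 1e-9)
        assert np.all(g.marker_index[g.marker_index >= 0] >= 0)


# ---------------------------------------------------------------------------
# meiosis: empirical recombination fraction matches Haldane


def test_empirical_recombination_matches_haldane():
    # two adjacent markers 20 cM apart; >= 100k gametes via a large backcross
    gmap = make_map({"1": 20.0}, {"1": 2})
    pop = breed_backcross("F1xDA", 100_000, gmap, seed=5)
    # maternal haplotype comes from the segregating F1 dam
    h = pop.maternal
    rec = np.mean(h[:, 0] != h[:, 1])
    r = haldane(20.0)
    se = np.sqrt(r * (1 - r) / h.shape[0])
    assert abs(rec - r) < 3 * se


def test_no_interference_independent_intervals():
    # switch events in adjacent 20 cM intervals are independent (Haldane)
    gmap = make_map({"1": 40.0}, {"1": 3})
    pop = breed_backcross("F1xDA", 100_000, gmap, seed=6)
    h = pop.maternal
    s1 = h[:, 0] != h[:, 1]
    s2 = h[:, 1] != h[:, 2]
    # correlation of indicator variables ~ 0
    rho = np.corrcoef(s1, s2)[0, 1]
    assert abs(rho) < 3 / np.sqrt(h.shape[0])


# ---------------------------------------------------------------------------
# cross designs and origin bookkeeping


@pytest.mark.parametrize("label,f1_parent,mito,y", [
    ("DAxF1", "father", D, P),
    ("F1xDA", "mother", D, D),
    ("PVGxF1", "father", P, P),
    ("F1xPVG", "mother", D, P),
])
def test_design_lineage_invariants(label, f1_parent, mito, y, rat_map):
    design = cross_design(label)
    assert design.f1_parent_sex == f1_parent
    pop = breed_backcross(label, 200, rat_map, seed=1)
    assert np.all(pop.mito == mito)
    assert np.all(pop.y == y)
    # the segregating (F1) parent's gamete varies; the inbred one does not
    segregating = pop.maternal if f1_parent == "mother" else pop.paternal
    fixed = pop.paternal if f1_parent == "mother" else pop.maternal
    assert len(np.unique(segregating)) == 2
    assert len(np.unique(fixed)) == 1
    assert np.unique(fixed)[0] == design.recurrent_strain
    # backcross genotypes: only hom-recurrent and het
    assert set(np.unique(pop.het())) <= {0, 1}
    # expected heterozygosity 0.5 at every marker
    het = pop.het().mean()
    assert abs(het - 0.5) < 3 * np.sqrt(0.25 / pop.maternal.size)


def test_unknown_cross_label_raises(rat_map):
    with pytest.raises(ValueError, match="unknown cross label"):
        breed_backcross("DAxDA", 10, rat_map)
    with pytest.raises(ValueError):
        breed_backcross("F1xDA", 0, rat_map)
    with pytest.raises(ValueError, match="breed_ail"):
        breed_backcross("AIL_G10", 10, rat_map)


def test_combine_and_subset_roundtrip(rat_map):
    a = breed_backcross("DAxF1", 30, rat_map, seed=1)
    b = breed_backcross("F1xDA", 20, rat_map, seed=2)
    pop = combine([a, b])
    assert pop.n == 50
    assert list(pop.cross[:30]) == ["DAxF1"] * 30
    sub = pop.subset(np.arange(30, 50))
    assert np.array_equal(sub.maternal, b.maternal)
    assert np.array_equal(sub.y, b.y)


def test_genotype_codes_noise_and_missing(rat_map, rng):
    pop = breed_backcross("F1xDA", 400, rat_map, seed=3)
    g0 = pop.genotype_codes()
    assert set(np.unique(g0)) <= {0, 1}
    g = pop.genotype_codes(error_prob=0.1, missing_prob=0.1, rng=rng)
    miss = np.mean(g == -1)
    assert abs(miss - 0.1) < 3 * np.sqrt(0.1 * 0.9 / g.size)
    flips = np.mean((g != g0) & (g != -1))
    assert 0.05 < flips < 0.12   # ~0.1 flipped, some then masked missing


# ---------------------------------------------------------------------------
# advanced intercross


def test_ail_g10_basics(rat_map):
    pop = breed_ail(10, generations=10, n_final=150, gmap=rat_map, seed=4)
    assert pop.n == 150
    assert set(pop.cross) == {"AIL_G10"}
    assert pop.origin is not None and pop.origin.min() >= 0
    assert pop.pedigree is not None
    assert set(pop.pedigree["generation"]) == set(range(2, 11))
    # intercross: all three genotype classes segregate
    dos = pop.dosage("P")
    assert set(np.unique(dos)) == {0, 1, 2}


def test_ail_f2_when_two_generations(rat_map):
    pop = breed_ail(10, generations=2, n_final=4000, gmap=rat_map, seed=4)
    # F2 genotype frequencies 1/4, 1/2, 1/4 (checked at one marker per
    # chromosome; genotypes at linked markers are not independent)
    dos = pop.dosage("P")
    first_cols = np.cumsum([0] + [len(rat_map.positions_cm(c))
                                  for c in rat_map.chromosomes[:-1]])
    for k, expected in ((0, 0.25), (1, 0.5), (2, 0.25)):
        frac = np.mean(dos[:, first_cols] == k)
        n_eff = dos.shape[0] * len(first_cols)
        assert abs(frac - expected) < 3 * np.sqrt(expected * (1 - expected)
                                                  / n_eff)


def test_ail_map_expansion(rat_map):
    # accumulated recombination: adjacent-marker haplotype switches are more
    # frequent in G10 gametes than in a single backcross meiosis
    bc = breed_backcross("F1xDA", 2000, rat_map, seed=7)
    ail = breed_ail(25, generations=10, n_final=2000, gmap=rat_map, seed=7)

    def switch_rate(pop):
        h = pop.maternal
        rates = []
        col = 0
        for chrom in pop.gmap.chromosomes:
            k = len(pop.gmap.positions_cm(chrom))
            blk = h[:, col:col + k]
            rates.append(np.mean(blk[:, :-1] != blk[:, 1:]))
            col += k
        return np.mean(rates)

    assert switch_rate(ail) > 1.5 * switch_rate(bc)


def test_ail_argument_validation(rat_map):
    with pytest.raises(ValueError):
        breed_ail(1, generations=10, gmap=rat_map)
    with pytest.raises(ValueError):
        breed_ail(10, generations=1, gmap=rat_map)
    with pytest.raises(ValueError):
        breed_ail(10, generations=10, gmap=None)


# ---------------------------------------------------------------------------
# substreams


def test_substream_deterministic_and_distinct():
    a1 = substream(11, "x").random(5)
    a2 = substream(11, "x").random(5)
    b = substream(11, "y").random(5)
    c = substream(12, "x").random(5)
    assert np.array_equal(a1, a2)
    assert not np.array_equal(a1, b)
    assert not np.array_equal(a1, c)


# ---------------------------------------------------------------------------
# phenotype model


def test_expected_incidence_closed_form():
    p = PhenotypeModelParams()
    assert p.expected_incidence() == pytest.approx(0.5)
    p2 = PhenotypeModelParams(incidence_threshold=1.0)
    assert p2.expected_incidence() == pytest.approx(stats.norm.sf(1.0))


def test_null_phenotypes_match_closed_form_incidence(rat_map):
    pop = breed_backcross("F1xDA", 4000, rat_map, seed=8)
    ph = simulate_phenotypes(pop, [], seed=8)
    inc = ph["INC"].mean()
    assert abs(inc - 0.5) < 3 * np.sqrt(0.25 / pop.n)
    # censoring policy: unaffected get onset = study end, DUR = MAX = 0
    un = ph[ph["INC"] == 0]
    assert (un["ONS"] == 40).all()
    assert (un["DUR"] == 0).all() and (un["MAX"] == 0).all()
    # affected animals: onset within study, positive duration and score
    af = ph[ph["INC"] == 1]
    assert (af["ONS"] >= 7).all() and (af["ONS"] <= 40).all()
    assert (af["DUR"] > 0).all() and (af["MAX"] > 0).all()


def test_phenotypes_monotone_in_liability(rat_map):
    # a strong additive QTL: het carriers of the risk allele are sicker
    pop = breed_backcross("F1xDA", 4000, rat_map, seed=9)
    q = QTLSpec("1", 100.0, "additive", 1.5, "P")
    ph = simulate_phenotypes(pop, [q], seed=9)
    col = np.argmin(np.abs(rat_map.positions_mb("1") - 100.0))
    carrier = pop.het()[:, col] == 1
    assert ph.loc[carrier, "INC"].mean() > ph.loc[~carrier, "INC"].mean()
    assert ph.loc[carrier, "WL"].mean() > ph.loc[~carrier, "WL"].mean()
    assert ph.loc[carrier, "MAX"].mean() > ph.loc[~carrier, "MAX"].mean()
    # earlier onset for sicker animals
    assert ph.loc[carrier, "ONS"].mean() < ph.loc[~carrier, "ONS"].mean()


def test_parental_expression_modes_follow_cross(rat_map):
    # a maternal_expressed QTL has an effect only where the F1 is the dam
    q = QTLSpec("1", 100.0, "maternal_expressed", 1.0, "P")
    col = np.argmin(np.abs(rat_map.positions_mb("1") - 100.0))
    for label, expressed in (("F1xDA", True), ("DAxF1", False)):
        pop = breed_backcross(label, 3000, rat_map, seed=10)
        ph = simulate_phenotypes(pop, [q], seed=10)
        het = pop.het()[:, col] == 1
        if expressed:
            diff = ph.loc[het, "WL"].mean() - ph.loc[~het, "WL"].mean()
            assert diff > 5.0   # wl_slope * effect = 10 with sd ~11
        else:
            t, p = stats.ttest_ind(ph.loc[het, "WL"], ph.loc[~het, "WL"])
            assert p > 1e-4     # no effect in the F1-father cross


def test_mitochondrial_mode_gated_by_lineage(rat_map):
    q = QTLSpec("1", 100.0, "mitochondrial", 1.0, "D")
    col = np.argmin(np.abs(rat_map.positions_mb("1") - 100.0))
    # PVGxF1 offspring carry PVG mitochondria: no effect of the D allele
    pop = breed_backcross("PVGxF1", 3000, rat_map, seed=11)
    ph = simulate_phenotypes(pop, [q], seed=11)
    het = pop.het()[:, col] == 1
    t, p = stats.ttest_ind(ph.loc[het, "WL"], ph.loc[~het, "WL"])
    assert p > 1e-4
    # F1xPVG offspring carry DA mitochondria: effect present
    pop2 = breed_backcross("F1xPVG", 3000, rat_map, seed=11)
    ph2 = simulate_phenotypes(pop2, [q], seed=11)
    het2 = pop2.het()[:, col] == 1
    assert ph2.loc[het2, "WL"].mean() - ph2.loc[~het2, "WL"].mean() > 5.0


def test_y_linked_mode_males_of_d_patriline_only(rat_map):
    q = QTLSpec("1", 100.0, "y_linked", 1.0, "D")
    # F1xDA has a DA-strain patriline; males are affected
    pop = breed_backcross("F1xDA", 4000, rat_map, seed=12)
    ph = simulate_phenotypes(pop, [q], seed=12)
    males = ph["sex"] == "M"
    assert ph.loc[males, "WL"].mean() - ph.loc[~males, "WL"].mean() > 5.0
    # DAxF1 males carry the PVG Y: no sex difference beyond noise
    pop2 = breed_backcross("DAxF1", 4000, rat_map, seed=12)
    ph2 = simulate_phenotypes(pop2, [q], seed=12)
    males2 = ph2["sex"] == "M"
    t, p = stats.ttest_ind(ph2.loc[males2, "WL"], ph2.loc[~males2, "WL"])
    assert p > 1e-4


def test_qtl_spec_validation():
    with pytest.raises(ValueError, match="mode"):
        QTLSpec("1", 10.0, "dominant", 0.5)
    with pytest.raises(ValueError, match="risk_strain"):
        QTLSpec("1", 10.0, "additive", 0.5, "Q")
    with pytest.raises(ValueError):
        QTLSpec("1", 10.0, "additive", np.nan)


def test_off_map_qtl_raises(rat_map):
    pop = breed_backcross("F1xDA", 10, rat_map, seed=1)
    with pytest.raises(ValueError, match="off the map"):
        simulate_phenotypes(pop, [QTLSpec("1", 1e5, "additive", 0.5)], seed=1)


def test_effect_from_varexp_closed_form():
    # backcross: varexp = (a^2/4) / (a^2/4 + 1)
    assert effect_from_varexp(0.2) == pytest.approx(1.0)
    a = effect_from_varexp(0.05)
    assert (a ** 2 / 4) / (a ** 2 / 4 + 1) == pytest.approx(0.05)
    with pytest.raises(ValueError):
        effect_from_varexp(1.0)


def test_weights_by_sex_match_model(rat_map):
    pop = breed_backcross("F1xDA", 4000, rat_map, seed=13)
    ph = simulate_phenotypes(pop, [], seed=13)
    f = ph[ph["sex"] == "F"]["weight"]
    m = ph[ph["sex"] == "M"]["weight"]
    assert abs(f.mean() - 106.0) < 3 * 12.0 / np.sqrt(len(f))
    assert abs(m.mean() - 170.0) < 3 * 22.0 / np.sqrt(len(m))
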