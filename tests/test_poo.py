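"""Parent-of-origin classification, validation and summary tables."""

import numpy as np
import pytest

from poqtl.datasets import load_interactions
from poqtl.genmap import default_rat_map
from poqtl.pipeline import results_sentences
from poqtl.poo import (classify_records, classify_study,
                       classify_transmission, detections_to_records,
                       interaction_pass, interaction_test, stratified_scan,
                       summarize_poo, validate_cross_population)
from poqtl.simulate import QTLSpec, breed_backcross, combine, \
    simulate_phenotypes


# -- transmission rule table --------------------------------------------------


def test_maternal_pattern_single_population():
    call = classify_transmission({"F1xDA": True, "DAxF1": False})
    assert call.call == "maternal"
    assert not call.mito_candidate and not call.y_candidate
    assert call.supporting == ("F1xDA",)


def test_maternal_pattern_both_populations():
    call = classify_transmission({"DAxF1": False, "F1xDA": True,
                                  "PVGxF1": False, "F1xPVG": True})
    assert call.call == "maternal"
    assert call.supporting == ("F1xDA", "F1xPVG")


def test_paternal_patterns():
    assert classify_transmission(
        {"DAxF1": True, "F1xDA": False}).call == "paternal"
    assert classify_transmission(
        {"DAxF1": True, "F1xDA": False,
         "PVGxF1": True, "F1xPVG": False}).call == "paternal"


def test_additive_pattern_is_not_parent_of_origin():
    call = classify_transmission({"DAxF1": True, "F1xDA": True})
    assert call.call == "none"
    assert not call.mito_candidate


def test_mitochondrial_pattern_flagged():
    """Detection in exactly the three crosses sharing the DA maternal
    lineage (all four observed) mimics a mitochondrial effect and must not
    be called parental."""
    call = classify_transmission({"DAxF1": True, "F1xDA": True,
                                  "PVGxF1": False, "F1xPVG": True})
    assert call.call == "none"
    assert call.mito_candidate
    assert call.flags == "mito"
    # the same detected set with one cross unobserved is NOT the mito split
    part = classify_transmission({"DAxF1": True, "F1xDA": True,
                                  "PVGxF1": None, "F1xPVG": True})
    assert not part.mito_candidate


def test_conflicting_sides_are_unresolved():
    """A maternal call in one population and a paternal call in the other
    cannot be reconciled."""
    call = classify_transmission({"DAxF1": False, "F1xDA": True,
                                  "PVGxF1": True, "F1xPVG": False})
    assert call.call == "unresolved"


def test_y_candidate_flag():
    """A male-only F1xDA-specific QTL splits along the patriline in DABC;
    absence in the PVGBC males (same PVG Y in both crosses) keeps the
    maternal reading but flags the Y confound."""
    det = {"DAxF1": False, "F1xDA": True, "PVGxF1": False, "F1xPVG": False}
    male = classify_transmission(det, sexes={"M"})
    assert male.call == "maternal" and male.y_candidate
    assert male.flags == "y"
    female = classify_transmission(det, sexes={"F"})
    assert not female.y_candidate
    # without PVGBC observations the confound cannot be excluded either way
    solo = classify_transmission({"DAxF1": False, "F1xDA": True},
                                 sexes={"M"})
    assert not solo.y_candidate


def test_no_detection_and_errors():
    assert classify_transmission({"DAxF1": False, "F1xDA": False}).call == \
        "none"
    with pytest.raises(ValueError, match="unknown cross"):
        classify_transmission({"AxB": True})
    with pytest.raises(ValueError, match="empty"):
        classify_transmission({"DAxF1": None, "F1xDA": None})


# -- published-table classification -------------------------------------------


@pytest.fixture(scope="module")
def study():
    return classify_study()


def test_headline_fractions(study):
    """Single-cross and final parent-of-origin percentages per population."""
    out = results_sentences(study)
    assert out["t1"] == {"value": pytest.approx(43.75), "n": 16}
    assert out["t2"] == {"value": pytest.approx(72.727272, rel=1e-6), "n": 11}
    assert out["t3"] == {"value": pytest.approx(37.5), "n": 16}
    assert out["t4"] == {"value": pytest.approx(54.545454, rel=1e-6), "n": 11}
    assert out["t5"] == {"value": pytest.approx(75.0), "n": 8}
    assert out["t6"] == {"value": pytest.approx(80.0), "n": 10}


def test_specific_published_calls(study):
    idx = study.qtls.set_index("qtl")
    # maternal across both populations
    assert idx.loc["4a:144", "call"] == "maternal"
    assert idx.loc["3:161", "call"] == "maternal"
    assert idx.loc["18:80", "call"] == "maternal"
    # paternal across both populations
    assert idx.loc["6:131", "call"] == "paternal"
    # mitochondrial-lineage split: flagged, not a parental call
    assert idx.loc["10a:23", "call"] == "none"
    assert bool(idx.loc["10a:23", "mito_candidate"])
    # maternal in DABC but paternal in PVGBC
    assert idx.loc["7b:50", "call"] == "unresolved"
    # additive in both populations
    assert idx.loc["10b:50", "call"] == "none"
    assert not bool(idx.loc["10b:50", "mito_candidate"])


def test_final_poo_rule(study):
    # single-cross + interaction + clean call
    assert study.final_poo("4a:144", "DABC")
    assert study.final_poo("6:131", "PVGBC")
    # the mito candidate fails despite being single-cross in PVGBC
    assert not study.final_poo("10a:23", "PVGBC")
    # additive QTLs have no per-population single-cross verdict
    assert not study.final_poo("12:25", "DABC")
    assert not study.final_poo("nonexistent", "DABC")


def test_summary_table(study):
    summary = summarize_poo(study)
    t = summary.set_index(["population", "category"])
    dabc = t.loc[("DABC", "Total")]
    assert dabc["total"] == 16
    assert dabc["n_poo"] == 6 and dabc["pct_poo"] == pytest.approx(37.5)
    assert dabc["n_maternal"] == 5
    pvg = t.loc[("PVGBC", "Total")]
    assert pvg["total"] == 11
    assert pvg["n_poo"] == 6
    assert pvg["n_maternal"] == 4
    shared = t.loc[("Shared", "Total")]
    assert shared["total"] == 7
    assert shared["n_poo"] == 4 and shared["n_maternal"] == 3
    # sex categories partition the totals
    for popn, total in (("DABC", 16), ("PVGBC", 11)):
        cats = t.loc[popn]
        parts = [int(cats.loc[c, "total"]) for c in
                 ("Females", "Males", "Females and Males") if c in cats.index]
        assert sum(parts) == total


def test_cross_population_validation(study):
    val = validate_cross_population(
        study.records[study.records["population"] == "DABC"],
        study.records[study.records["population"] == "PVGBC"])
    assert len(val) == 8                       # sex-specific single-cross rows
    assert int(val["detected_in_other"].sum()) == 6
    assert int(val["transmission_concordant"].sum()) == 5
    # the one discordant validated QTL switches parental side
    disc = val[val["detected_in_other"] & ~val["transmission_concordant"]]
    assert list(disc["qtl"]) == ["7b:50"]


def test_interaction_pass_rule():
    ipass = interaction_pass(load_interactions()).set_index("qtl")
    assert int(ipass["passes"].sum()) == 8
    assert not ipass.loc["10a:23", "passes"]    # nothing significant
    assert ipass.loc["10a:23", "n_significant"] == 0
    assert not ipass.loc["7b:50", "passes"]     # only one phenotype
    assert ipass.loc["7b:50", "n_significant"] == 1
    assert ipass.loc["4a:144", "passes"]
    # stricter alpha removes candidates, never adds them
    strict = interaction_pass(load_interactions(), alpha=0.01)
    assert int(strict["passes"].sum()) <= 8


# -- record merging -----------------------------------------------------------


def test_classify_records_positional_merging():
    import pandas as pd
    records = pd.DataFrame({
        "chrom": ["4", "4", "4"],
        "pos_mb": [144.0, 150.0, 185.0],
        "population": ["DABC", "PVGBC", "DABC"],
        "sex": ["F", "F", "F"],
        "det_DAxF1": [False, np.nan, True],
        "det_F1xDA": [True, np.nan, True],
        "det_PVGxF1": [np.nan, False, np.nan],
        "det_F1xPVG": [np.nan, True, np.nan],
    })
    out = classify_records(records, merge_mb=20.0)
    # rows at 144 and 150 merge into one maternal QTL; 185 stays separate
    assert len(out) == 2
    merged = out[out["pos_mb"] < 160].iloc[0]
    assert merged["call"] == "maternal"
    assert merged["populations"] == "DABC,PVGBC"
    far = out[out["pos_mb"] > 160].iloc[0]
    assert far["call"] == "none"               # detected in both crosses


# -- stratified scans on simulated populations --------------------------------


@pytest.fixture(scope="module")
def maternal_sim():
    gmap = default_rat_map()
    pop = combine([breed_backcross("DAxF1", 110, gmap, seed=61),
                   breed_backcross("F1xDA", 110, gmap, seed=62)])
    qtl = QTLSpec(chrom="4", pos_mb=144.0, mode="maternal_expressed",
                  effect=1.2, risk_strain="P")
    phenos = simulate_phenotypes(pop, [qtl], seed=63)
    return pop, phenos


def test_stratified_scan_recovers_maternal_qtl(maternal_sim):
    pop, phenos = maternal_sim
    res = stratified_scan(pop, phenos, merge_mb=40.0)
    det = res.detections
    hits = det[(det["chrom"] == "4") & ((det["pos_mb"] - 144).abs() < 40)]
    assert len(hits) == 1
    row = hits.iloc[0]
    # expressed only when the F1 is the mother
    assert bool(row["det_F1xDA"]) and not bool(row["det_DAxF1"])
    records = detections_to_records(hits, "DABC")
    call = classify_records(records, merge_mb=40.0).iloc[0]
    assert call["call"] == "maternal"
    assert call["verdict_DABC"] == "F1xDA"


def test_interaction_test_on_simulated_qtl(maternal_sim):
    pop, phenos = maternal_sim
    qtl = ("4", 144.0)
    table = interaction_test(pop, phenos, [qtl], [qtl], n_imp=16, seed=64)
    assert list(table.index) == ["INC", "MAX", "DUR", "ONS", "WL"]
    # a maternally expressed effect makes the QTL x cross term significant
    # for at least two phenotypes (the published candidate rule)
    assert int((table["4:144"] <= 0.05).sum()) >= 2
    with pytest.raises(ValueError, match="candidates not in the model"):
        interaction_test(pop, phenos, [qtl], [("9", 1.0)])


def test_small_stratum_warning(small_map):
    pop = combine([breed_backcross("DAxF1", 10, small_map, seed=65),
                   breed_backcross("F1xDA", 40, small_map, seed=66)])
    phenos = simulate_phenotypes(pop, [], seed=67)
    res = stratified_scan(pop, phenos, min_stratum=30)
    assert any("DAxF1" in w for w in res.warnings)
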