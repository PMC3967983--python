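"""Parent-of-origin inference from reciprocal-cross detection patterns.

The reciprocal backcross design turns imprinting-like transmission into a
detection pattern: a variant expressed only from the maternal copy can be
mapped only in crosses where the F1 hybrid is the mother (F1xDA, F1xPVG),
and a paternally expressed variant only where the F1 is the father (DAxF1,
PVGxF1).  A QTL detected in both crosses of a population is an ordinary
additive QTL ("ALL").  Two lineage confounds mimic these patterns:
mitochondria follow the maternal lineage (only PVGxF1 offspring carry PVG
mitochondria), and in DABC males the Y strain segregates between the
reciprocal crosses.

This module assembles per-cross detection patterns from stratified scans
(or from the published tables), classifies transmission, tests cross-by-QTL
interactions via the multiple-imputation QTL model, validates calls across
the two independent populations, and produces the summary table of
parent-of-origin effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import datasets
from .genoprob import calc_genoprob, sim_geno
from .mqm import QTLModel, QTLTerm, fit_qtl
from .scan import ScanResult, scan_hk
from .simulate import (F1_FATHER_CROSSES, F1_MOTHER_CROSSES, POPULATIONS,
                       SimPopulation)

ALL_CROSSES = ("DAxF1", "F1xDA", "PVGxF1", "F1xPVG")
#: crosses whose offspring carry DA mitochondria
D_MITO_CROSSES = frozenset({"DAxF1", "F1xDA", "F1xPVG"})
CROSS_SIDE = {c: "maternal" for c in F1_MOTHER_CROSSES}
CROSS_SIDE.update({c: "paternal" for c in F1_FATHER_CROSSES})
CROSS_POP = {c: p for p, cs in POPULATIONS.items() for c in cs}

DET_COLS = {c: f"det_{c}" for c in ALL_CROSSES}


@dataclass(frozen=True)
class TransmissionCall:
    """Transmission classification of one QTL across reciprocal crosses."""

    call: str                      # maternal | paternal | none | unresolved
    mito_candidate: bool = False
    y_candidate: bool = False
    supporting: tuple = ()

    @property
    def flags(self) -> str:
        out = []
        if self.mito_candidate:
            out.append("mito")
        if self.y_candidate:
            out.append("y")
        return ",".join(out)


def _population_verdict(detected: set, observed: set, pop: str):
    """'ALL', a single cross label, 'none', or None if unobserved."""
    crosses = set(POPULATIONS[pop])
    obs = observed & crosses
    if not obs:
        return None
    det = detected & crosses
    if det == crosses:
        return "ALL"
    if len(det) == 1:
        return next(iter(det))
    return "none"


def classify_transmission(detected: dict, sexes: set | None = None,
                          ) -> TransmissionCall:
    """Classify a QTL's transmission from its four-cross detection pattern.

    ``detected`` maps cross label -> True/False/None (None = not studied).
    Detection confined to F1-mother crosses is maternal transmission,
    confined to F1-father crosses paternal; both crosses of a population is
    an additive pattern (call 'none'); single-cross calls that point to
    opposite parental sides in the two populations are unresolved.  A
    pattern that splits the four crosses exactly along the mitochondrial
    lineage is flagged ``mito_candidate``; a male-only pattern that splits
    along the patriline is flagged ``y_candidate``.
    """
    bad = set(detected) - set(ALL_CROSSES)
    if bad:
        raise ValueError(f"unknown cross labels {sorted(bad)}")
    observed = {c for c, v in detected.items() if v is not None}
    if not observed:
        raise ValueError("empty detection pattern")
    S = {c for c, v in detected.items() if v}
    supporting = tuple(sorted(S))

    mito = observed == set(ALL_CROSSES) and S == set(D_MITO_CROSSES)
    y_cand = (S == {"F1xDA"} and (sexes is not None and sexes == {"M"})
              and {"PVGxF1", "F1xPVG"} <= observed)

    if not S:
        return TransmissionCall("none", supporting=supporting)
    if mito:
        return TransmissionCall("none", mito_candidate=True,
                                supporting=supporting)
    if S <= set(F1_MOTHER_CROSSES):
        return TransmissionCall("maternal", y_candidate=y_cand,
                                supporting=supporting)
    if S <= set(F1_FATHER_CROSSES):
        return TransmissionCall("paternal", supporting=supporting)
    # mixed sides: additive within a population, or contradictory
    verdicts = {p: _population_verdict(S, observed, p) for p in POPULATIONS}
    single_sides = {CROSS_SIDE[v] for v in verdicts.values()
                    if v in CROSS_SIDE}
    if len(single_sides) == 2:
        return TransmissionCall("unresolved", supporting=supporting)
    return TransmissionCall("none", supporting=supporting)


# ---------------------------------------------------------------------------
# detection records and QTL-level classification


def _merge_qtls(records: pd.DataFrame, merge_mb: float) -> pd.Series:
    """Group detection records into QTL identities.

    Records carrying an explicit ``qtl`` id keep it; otherwise records on
    the same chromosome within the merge radius share an id.
    """
    if "qtl" in records.columns and records["qtl"].notna().all():
        return records["qtl"]
    ids = pd.Series(index=records.index, dtype=object)
    for chrom, sub in records.groupby("chrom"):
        sub = sub.sort_values("pos_mb")
        current, anchor = None, None
        for idx, row in sub.iterrows():
            if current is None or row["pos_mb"] - anchor > merge_mb:
                current = f"{chrom}:{row['pos_mb']:g}"
                anchor = row["pos_mb"]
            ids[idx] = current
    return ids


def classify_records(records: pd.DataFrame, merge_mb: float = 20.0,
                     ) -> pd.DataFrame:
    """QTL-level transmission classification from detection records.

    ``records`` has one row per (population, sex) detection pattern with
    columns ``chrom``, ``pos_mb``, ``population``, ``sex``, optional
    ``qtl`` id, and ``det_<cross>`` booleans (NaN where the cross was not
    studied).  Patterns of the same QTL are combined across populations and
    sexes before classification, so a call can draw on both independent
    populations, as in the published tables.
    """
    records = records.copy()
    records["qtl"] = _merge_qtls(records, merge_mb)
    rows = []
    for qtl, sub in records.groupby("qtl", sort=False):
        detected: dict = {}
        for c in ALL_CROSSES:
            col = DET_COLS[c]
            if col not in sub.columns:
                detected[c] = None
                continue
            vals = sub[col].dropna()
            detected[c] = None if vals.empty else bool(vals.any())
        sexes = {s for s in sub["sex"] if s in ("F", "M")}
        det_sexes = set()
        for _, r in sub.iterrows():
            if any(r.get(DET_COLS[c]) is True or r.get(DET_COLS[c]) == 1.0
                   for c in ALL_CROSSES):
                if r["sex"] in ("F", "M"):
                    det_sexes.add(r["sex"])
        call = classify_transmission(detected, sexes=det_sexes or sexes or None)
        verdicts = {
            p: _population_verdict(
                {c for c, v in detected.items() if v},
                {c for c, v in detected.items() if v is not None}, p)
            for p in POPULATIONS}
        rows.append({
            "qtl": qtl,
            "chrom": sub["chrom"].iloc[0],
            "pos_mb": float(sub["pos_mb"].astype(float).mean()),
            "populations": ",".join(sorted(set(sub["population"]))),
            "sexes": "".join(sorted(set(sub["sex"]))),
            "call": call.call,
            "mito_candidate": call.mito_candidate,
            "y_candidate": call.y_candidate,
            "supporting": ",".join(call.supporting),
            "verdict_DABC": verdicts["DABC"],
            "verdict_PVGBC": verdicts["PVGBC"],
        })
    return pd.DataFrame(rows)


def interaction_pass(interactions: pd.DataFrame, alpha: float = 0.05,
                     min_phenos: int = 2) -> pd.DataFrame:
    """Apply the interaction rule to a QTL x phenotype p-value table.

    A candidate passes when its cross(origin)-by-QTL interaction is
    significant (p <= alpha) for at least ``min_phenos`` phenotypes;
    untestable entries (NaN) never count.
    """
    pcols = [c for c in interactions.columns
             if c not in ("qtl", "population")]
    n_sig = (interactions[pcols] <= alpha).sum(axis=1)
    return pd.DataFrame({
        "qtl": interactions["qtl"],
        "n_significant": n_sig.astype(int),
        "passes": (n_sig >= min_phenos).to_numpy(),
    })


@dataclass
class StudyClassification:
    """Full classification of a two-population reciprocal-cross study."""

    qtls: pd.DataFrame               # QTL-level calls (classify_records)
    records: pd.DataFrame            # row-level detection records
    interactions: pd.DataFrame       # interaction_pass output
    alpha: float
    min_phenos: int

    def final_poo(self, qtl: str, population: str) -> bool:
        row = self.qtls[self.qtls["qtl"] == qtl]
        if row.empty:
            return False
        row = row.iloc[0]
        verdict = row[f"verdict_{population}"]
        single = verdict in CROSS_SIDE
        ok_int = bool(
            self.interactions.loc[self.interactions["qtl"] == qtl, "passes"]
            .any())
        clean = (row["call"] in ("maternal", "paternal")
                 and not row["mito_candidate"])
        return bool(single and ok_int and clean)


def classify_study(dabc: pd.DataFrame | None = None,
                   pvgbc: pd.DataFrame | None = None,
                   interactions: pd.DataFrame | None = None,
                   alpha: float = 0.05, min_phenos: int = 2,
                   merge_mb: float = 20.0) -> StudyClassification:
    """Classify a study from per-QTL effect tables.

    Defaults to the bundled transcriptions of the published tables.  Each
    effect-table row contributes a detection record: ``cross = ALL`` marks
    detection in both reciprocal crosses, a cross label marks single-cross
    detection, and ``POP`` marks a QTL significant only in the entire
    population (observed but not detected in either cross).
    """
    if dabc is None:
        dabc = datasets.load_qtl_effects("DABC")
    if pvgbc is None:
        pvgbc = datasets.load_qtl_effects("PVGBC")
    if interactions is None:
        interactions = datasets.load_interactions()
    records = pd.concat(
        [_effects_to_records(dabc), _effects_to_records(pvgbc)],
        ignore_index=True)
    qtls = classify_records(records, merge_mb=merge_mb)
    ipass = interaction_pass(interactions, alpha=alpha, min_phenos=min_phenos)
    return StudyClassification(qtls=qtls, records=records,
                               interactions=ipass, alpha=alpha,
                               min_phenos=min_phenos)


def _effects_to_records(effects: pd.DataFrame) -> pd.DataFrame:
    pop = effects["population"].iloc[0]
    crosses = POPULATIONS[pop]
    rows = []
    for _, r in effects.iterrows():
        det = {DET_COLS[c]: np.nan for c in ALL_CROSSES}
        for c in crosses:
            det[DET_COLS[c]] = False
        if r["cross"] == "ALL":
            for c in crosses:
                det[DET_COLS[c]] = True
        elif r["cross"] in crosses:
            det[DET_COLS[r["cross"]]] = True
        elif r["cross"] != "POP":
            raise ValueError(f"unknown cross field {r['cross']!r}")
        rows.append({"qtl": r["qtl"], "chrom": r["chrom"],
                     "pos_mb": float(r["pos_mb"]), "population": pop,
                     "sex": r["sex"], "row_cross": r["cross"],
                     "shared": r.get("shared", "no"), **det})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cross-population validation


def validate_cross_population(records_a: pd.DataFrame,
                              records_b: pd.DataFrame,
                              merge_mb: float = 20.0) -> pd.DataFrame:
    """Validate single-cross detections of one population in the other.

    Counting is sex-specific on side A: every (QTL, sex) record identified
    in a single reciprocal cross is checked for a single-cross detection of
    the same QTL (matched by id, or chromosome + position within the merge
    radius) in the other population, and for concordant parental side.
    """
    out = []
    for _, r in records_a.iterrows():
        if r["row_cross"] not in CROSS_SIDE:
            continue
        side_a = CROSS_SIDE[r["row_cross"]]
        if "qtl" in records_b.columns:
            match = records_b[records_b["qtl"] == r["qtl"]]
        else:
            match = records_b[
                (records_b["chrom"] == r["chrom"])
                & ((records_b["pos_mb"] - r["pos_mb"]).abs() <= merge_mb)]
        match_single = match[match["row_cross"].isin(CROSS_SIDE)]
        detected = not match_single.empty
        sides_b = {CROSS_SIDE[c] for c in match_single["row_cross"]}
        concordant = detected and sides_b == {side_a}
        out.append({"qtl": r["qtl"], "sex": r["sex"],
                    "cross": r["row_cross"], "side": side_a,
                    "detected_in_other": detected,
                    "transmission_concordant": bool(concordant)})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# summary table


def _sex_category(sexes: set) -> str:
    if sexes == {"F"}:
        return "Females"
    if sexes == {"M"}:
        return "Males"
    return "Females and Males"


def summarize_poo(study: StudyClassification) -> pd.DataFrame:
    """Summary of parent-of-origin effects per population and sex category.

    For each population: total unique QTLs, the percentage with a final
    parent-of-origin call (single-cross detection, significant interaction
    for at least ``min_phenos`` phenotypes, no disqualifying confound), and
    the percentage of those with maternal transmission; plus a row for the
    QTLs shared between the two populations.
    """
    rows = []
    share_ids = set(
        self_rec["qtl"] for _, self_rec in study.records.iterrows()
        if str(self_rec.get("shared", "no")) == "yes")
    for pop in POPULATIONS:
        pop_rec = study.records[study.records["population"] == pop]
        if pop_rec.empty:
            continue
        per_qtl = {}
        for qtl, sub in pop_rec.groupby("qtl", sort=False):
            sexes = set(sub["sex"])
            cat = ("Females and Males" if "both" in sexes
                   else _sex_category(sexes))
            per_qtl[qtl] = cat
        cats = ["Females", "Males", "Females and Males"]
        for cat in cats + ["Total"]:
            qtls = [q for q, c in per_qtl.items() if cat in (c, "Total")]
            if not qtls:
                continue
            poo = [q for q in qtls if study.final_poo(q, pop)]
            mat = [q for q in poo
                   if study.qtls.set_index("qtl").loc[q, "call"] == "maternal"]
            rows.append(_summary_row(pop, cat, qtls, poo, mat))
    # shared QTLs: PoO in either population
    if share_ids:
        qtls = sorted(share_ids)
        poo = [q for q in qtls
               if any(study.final_poo(q, p) for p in POPULATIONS)]
        mat = [q for q in poo
               if study.qtls.set_index("qtl").loc[q, "call"] == "maternal"]
        rows.append(_summary_row("Shared", "Total", qtls, poo, mat))
    return pd.DataFrame(rows)


def _summary_row(pop, cat, qtls, poo, mat):
    n, k, m = len(qtls), len(poo), len(mat)
    return {"population": pop, "category": cat, "total": n,
            "n_poo": k, "pct_poo": 100.0 * k / n if n else np.nan,
            "n_maternal": m,
            "pct_maternal": 100.0 * m / k if k else np.nan}


# ---------------------------------------------------------------------------
# stratified scanning of simulated/observed populations


@dataclass
class StratifiedScanResult:
    """Per-cross scans plus the merged QTL detection table."""

    scans: dict                      # (stratum, phenotype) -> ScanResult
    detections: pd.DataFrame         # one row per merged QTL
    thresholds: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


def _find_peaks(res: ScanResult, locate_lod: float, merge_mb: float):
    peaks = []
    for chrom, sub in res.table.groupby("chrom", sort=False):
        lod = sub["lod"].to_numpy()
        mb = sub["pos_mb"].to_numpy()
        above = lod >= locate_lod
        if not above.any():
            continue
        # cluster contiguous runs of significant grid positions; separate
        # runs still count as one cluster within the merge radius
        idx = np.flatnonzero(above)
        start = idx[0]
        prev = idx[0]
        clusters = []
        for i in idx[1:]:
            if i > prev + 1 and mb[i] - mb[prev] > merge_mb:
                clusters.append((start, prev))
                start = i
            prev = i
        clusters.append((start, prev))
        for a, b in clusters:
            seg = slice(a, b + 1)
            k = a + int(np.argmax(lod[seg]))
            peaks.append((str(chrom), float(mb[k]), float(lod[k])))
    return peaks


def stratified_scan(pop: SimPopulation, phenos: pd.DataFrame,
                    pheno_names=("ONS", "MAX", "WL"),
                    locate_lod: float = 1.3, detect_alpha: float = 0.05,
                    merge_mb: float = 20.0, step_mb: float = 0.0,
                    error_prob: float = 1e-4, min_stratum: int = 30,
                    include_pooled: bool = True) -> StratifiedScanResult:
    """Scan each reciprocal cross separately and assemble detection patterns.

    QTLs are located wherever any per-cross or pooled scan reaches
    ``locate_lod`` (the nominal threshold by default); peaks within the
    merge radius are treated as one QTL.  The per-cross detection pattern
    then applies a pointwise test (p <= ``detect_alpha`` for at least one
    scanned phenotype) at the merged peak, mirroring how per-cross allelic
    effects are reported in reciprocal-cross studies.
    """
    strata = list(dict.fromkeys(pop.cross))
    warnings = []
    probs_all = calc_genoprob(pop.genotype_codes(), pop.gmap,
                              step_mb=step_mb, error_prob=error_prob)
    masks = {s: np.flatnonzero(pop.cross == s) for s in strata}
    for s, m in masks.items():
        if len(m) < min_stratum:
            warnings.append(f"stratum {s} has only {len(m)} individuals; "
                            "detection power is limited")
    scans: dict = {}
    for s in strata:
        sub = probs_all.subset(masks[s])
        for ph in pheno_names:
            y = phenos[ph].to_numpy(float)[masks[s]]
            scans[(s, ph)] = scan_hk(sub, y, pheno_name=ph)
    if include_pooled:
        for ph in pheno_names:
            scans[("pooled", ph)] = scan_hk(
                probs_all, phenos[ph].to_numpy(float), pheno_name=ph)

    # locate candidate QTLs across all scans; peaks closer than the merge
    # radius (or one grid step, whichever is larger — positions cannot be
    # resolved below the grid spacing) are one QTL
    spacing = {}
    for chrom, sub in probs_all.positions.groupby("chrom", sort=False):
        mb = np.sort(sub["pos_mb"].to_numpy(float))
        spacing[str(chrom)] = float(np.diff(mb).max()) if len(mb) > 1 else 0.0
    merged: list[dict] = []
    all_peaks = []
    for key, res in scans.items():
        for chrom, mb, lod in _find_peaks(res, locate_lod, merge_mb):
            all_peaks.append((lod, chrom, mb))
    for lod, chrom, mb in sorted(all_peaks, reverse=True):
        radius = max(merge_mb, spacing.get(chrom, 0.0) * 1.01)
        for q in merged:
            if q["chrom"] == chrom and abs(q["pos_mb"] - mb) <= radius:
                break
        else:
            merged.append({"chrom": chrom, "pos_mb": mb, "peak_lod": lod})

    rows = []
    for q in merged:
        row = {"chrom": q["chrom"], "pos_mb": q["pos_mb"],
               "peak_lod": q["peak_lod"]}
        for s in strata:
            best_p, best_lod = 1.0, 0.0
            for ph in pheno_names:
                res = scans[(s, ph)]
                lod = res.lod_at(q["chrom"], q["pos_mb"])
                p = float(res.pointwise_p(lod))
                if p < best_p:
                    best_p, best_lod = p, lod
            row[DET_COLS[s] if s in DET_COLS else f"det_{s}"] = \
                best_p <= detect_alpha
            row[f"lod_{s}"] = best_lod
            row[f"p_{s}"] = best_p
        rows.append(row)
    detections = pd.DataFrame(rows)
    return StratifiedScanResult(scans=scans, detections=detections,
                                warnings=warnings)


def detections_to_records(detections: pd.DataFrame, population: str,
                          sex: str = "FM") -> pd.DataFrame:
    """Convert a stratified-scan detection table into classification records."""
    crosses = POPULATIONS[population]
    rows = []
    for _, r in detections.iterrows():
        det = {DET_COLS[c]: np.nan for c in ALL_CROSSES}
        for c in crosses:
            det[DET_COLS[c]] = bool(r[DET_COLS[c]])
        dets = [c for c in crosses if r[DET_COLS[c]]]
        row_cross = ("ALL" if len(dets) == 2
                     else dets[0] if len(dets) == 1 else "POP")
        rows.append({"qtl": np.nan, "chrom": r["chrom"],
                     "pos_mb": float(r["pos_mb"]), "population": population,
                     "sex": sex, "row_cross": row_cross, "shared": "no",
                     **det})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# interaction testing on populations


def interaction_test(pop: SimPopulation, phenos: pd.DataFrame,
                     qtl_list: list[tuple], candidates: list[tuple],
                     pheno_names=("INC", "MAX", "DUR", "ONS", "WL"),
                     covariate: str = "cross", n_imp: int = 128,
                     step_mb: float = 0.0, error_prob: float = 1e-4,
                     seed: int = 0) -> pd.DataFrame:
    """Cross-by-QTL (or origin-by-QTL) interaction p-values.

    Builds the full additive model of every QTL in ``qtl_list`` plus the
    covariate plus covariate-interaction terms for the ``candidates``
    (positions as (chrom, pos_mb)), fits it over genotype imputations, and
    reports the drop-one p-value of each interaction term for each
    phenotype.
    """
    cand_names = {f"{c}:{p:g}" for c, p in candidates}
    qtl_names = {f"{c}:{p:g}" for c, p in qtl_list}
    missing = cand_names - qtl_names
    if missing:
        raise ValueError(f"candidates not in the model: {sorted(missing)}")
    imput = sim_geno(pop.genotype_codes(), pop.gmap, n_draws=n_imp,
                     step_mb=step_mb, error_prob=error_prob, seed=seed)
    if covariate == "cross":
        labels = sorted(set(pop.cross))
        if len(labels) < 2:
            raise ValueError("interaction test needs at least two strata")
        cov = pd.DataFrame({"cross": pd.Categorical(pop.cross).codes.astype(float)})
        covname = "cross"
    elif covariate == "origin":
        if pop.origin is None:
            raise ValueError("population has no origin labels")
        cov = pd.DataFrame({"origin": np.asarray(pop.origin, dtype=float)})
        covname = "origin"
    else:
        cov = pd.DataFrame({covariate: phenos[covariate].to_numpy(float)})
        covname = covariate
    model = QTLModel(
        qtls=[QTLTerm(str(c), float(p)) for c, p in qtl_list],
        covariates=[covname],
        interactions=[(f"{c}:{p:g}", covname) for c, p in candidates])
    out = []
    for ph in pheno_names:
        fit = fit_qtl(model, imput, phenos[ph].to_numpy(float), covar=cov)
        row = {"pheno": ph}
        for c, p in candidates:
            term = f"{c}:{p:g}x{covname}"
            t = fit.drop_table[fit.drop_table["term"] == term]
            row[f"{c}:{p:g}"] = float(t["p"].iloc[0])
        out.append(row)
    return pd.DataFrame(out).set_index("pheno")
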