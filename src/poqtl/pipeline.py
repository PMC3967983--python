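"""Orchestrating pipeline: from cross data to a report directory.

The pipeline runs the analysis sequence of a reciprocal-cross QTL study —
genome scans per phenotype, permutation thresholds, multiple-QTL model
selection, stratified per-cross scans, transmission classification and
interaction testing — and writes every numeric table plus a line-oriented
log (JSON metadata header with seeds and library versions, then one line
per stage).  In fixtures-only mode it skips all computation on genotypes
and instead reproduces the study-level summary table from the bundled
per-QTL effect tables.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__, datasets, poo
from .genoprob import calc_genoprob
from .io import CrossData, RunConfig, population_to_cross_data, read_cross, \
    write_cross
from .mqm import fit_qtl, forward_backward_select
from .genoprob import sim_geno
from .phenostats import GroupSummary, fisher_incidence, ttest_from_summary
from .scan import permute_threshold, scan_hk
from .simulate import (POPULATIONS, QTLSpec, breed_backcross, combine,
                       simulate_phenotypes, substream)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


# ---------------------------------------------------------------------------
# fixture-derived summaries


def results_sentences(study: poo.StudyClassification | None = None) -> dict:
    """The study-level headline percentages, as {id: {value, n}}.

    t1/t2: percentage of unique QTLs identified in a single reciprocal
    cross, per population; t3/t4: percentage with a final parent-of-origin
    call; t5: percentage of sex-specific single-cross detections in the
    first population validated in the second; t6: percentage of candidates
    passing the interaction rule.
    """
    if study is None:
        study = poo.classify_study()
    out = {}
    for tid_single, tid_final, popn in (("t1", "t3", "DABC"),
                                        ("t2", "t4", "PVGBC")):
        rec = study.records[study.records["population"] == popn]
        qtls = list(dict.fromkeys(rec["qtl"]))
        idx = study.qtls.set_index("qtl")
        single = [q for q in qtls
                  if idx.loc[q, f"verdict_{popn}"] in poo.CROSS_SIDE]
        final = [q for q in qtls if study.final_poo(q, popn)]
        out[tid_single] = {"value": 100.0 * len(single) / len(qtls),
                           "n": len(qtls)}
        out[tid_final] = {"value": 100.0 * len(final) / len(qtls),
                          "n": len(qtls)}
    val = poo.validate_cross_population(
        study.records[study.records["population"] == "DABC"],
        study.records[study.records["population"] == "PVGBC"])
    out["t5"] = {"value": 100.0 * val["detected_in_other"].mean(),
                 "n": len(val)}
    out["t6"] = {"value": 100.0 * study.interactions["passes"].mean(),
                 "n": len(study.interactions)}
    return out


def recompute_table1(summaries: pd.DataFrame | None = None,
                     sex: str | None = None) -> pd.DataFrame:
    """Recompute reciprocal-cross comparison p-values from group summaries.

    Continuous phenotypes get the pooled-variance t-test from the printed
    mean/SD/n; incidence gets Fisher's exact test on back-computed counts.
    """
    if summaries is None:
        summaries = datasets.load_reciprocal_summaries()
    rows = []
    for (popn, sx), sub in summaries.groupby(["population", "sex"]):
        if sex is not None and sx != sex:
            continue
        crosses = sorted(set(sub["cross"]))
        if len(crosses) != 2:
            raise ValueError(f"expected two crosses for {popn}/{sx}")
        a, b = crosses
        for pheno, psub in sub.groupby("phenotype", sort=False):
            ga = psub[psub["cross"] == a].iloc[0]
            gb = psub[psub["cross"] == b].iloc[0]
            if pheno == "INC":
                p = fisher_incidence(
                    int(round(ga["mean"] * ga["n"])), int(ga["n"]),
                    int(round(gb["mean"] * gb["n"])), int(gb["n"]))
                t = np.nan
            else:
                t, _, p = ttest_from_summary(
                    GroupSummary(ga["mean"], ga["sd"], int(ga["n"])),
                    GroupSummary(gb["mean"], gb["sd"], int(gb["n"])))
            rows.append({"population": popn, "sex": sx, "phenotype": pheno,
                         "cross_a": a, "cross_b": b,
                         "mean_a": ga["mean"], "mean_b": gb["mean"],
                         "t": t, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# log


class _Log:
    def __init__(self, path: Path, config: RunConfig):
        self.fh = path.open("w")
        header = {
            "tool": "poqtl", "version": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "config": config.to_dict(),
        }
        self.fh.write(json.dumps(header, sort_keys=True) + "\n")

    def line(self, stage: str, msg: str):
        self.fh.write(f"[{stage}] {msg}\n")

    def close(self):
        self.fh.close()


def _write(df: pd.DataFrame, path: Path, log: _Log, stage: str):
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    log.line(stage, f"wrote {path.name} ({len(df)} rows)")


# ---------------------------------------------------------------------------
# population assembly


class _ObservedPopulation:
    """Adapter giving CrossData the population interface the scans need."""

    def __init__(self, data: CrossData):
        self._geno = data.genotypes
        self.gmap = data.gmap
        self.cross = data.labels["cross"].to_numpy()
        self.sex = (data.labels["sex"].to_numpy() == "M").astype(int)
        self.origin = None
        self.n = data.genotypes.shape[0]

    def genotype_codes(self, error_prob: float = 0.0,
                       missing_prob: float = 0.0, rng=None):
        return self._geno


def _simulate_population(config: RunConfig, log: _Log):
    recipe = dict(config.simulate)
    popn = recipe.get("population", "DABC")
    if popn not in POPULATIONS:
        raise ValueError(f"unknown population {popn!r}")
    n = int(recipe.get("n_per_cross", 110))
    qtls = [QTLSpec(str(q["chrom"]), float(q["pos_mb"]), q["mode"],
                    float(q["effect"]), q.get("risk_strain", "P"))
            for q in recipe.get("qtls", [])]
    from .genmap import default_rat_map
    gmap = default_rat_map()
    rng = substream(config.seed, "pipeline")
    pops = [breed_backcross(c, n, gmap, seed=int(rng.integers(0, 2**31 - 1)))
            for c in POPULATIONS[popn]]
    pop = combine(pops)
    phenos = simulate_phenotypes(pop, qtls,
                                 seed=int(rng.integers(0, 2**31 - 1)))
    log.line("simulate", f"{popn}: {pop.n} individuals, {len(qtls)} QTLs, "
                         f"crosses {POPULATIONS[popn]}")
    return popn, pop, phenos


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: RunConfig, out_dir: str | Path,
                 cross_files=(), fixtures_only: bool = False) -> Path:
    """Run the full analysis and write a report directory.

    Deterministic given ``config.seed``.  Either analyse existing cross
    files, simulate a population from ``config.simulate``, or — with
    ``fixtures_only`` — reproduce the study-level summaries from the
    bundled published tables without touching any genotypes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    log = _Log(out / "run.log", config)
    try:
        _stage_fixtures(config, out, log)
        if not fixtures_only:
            pops = []
            for f in cross_files:
                try:
                    data = read_cross(f)
                except Exception as e:
                    raise PipelineError("read", f"{f}: {e}") from e
                name = Path(f).stem
                pops.append((name, _ObservedPopulation(data), data.phenos))
                log.line("read", f"{name}: {data.n} individuals, "
                                 f"{data.gmap.n_markers} markers")
            if config.simulate is not None:
                try:
                    name, pop, phenos = _simulate_population(config, log)
                except Exception as e:
                    raise PipelineError("simulate", str(e)) from e
                geno, gmap, ph, labels, meta = population_to_cross_data(
                    pop, phenos, metadata={"design": name,
                                           "seed": str(config.seed)})
                write_cross(out / f"{name}_simulated.csv", geno, gmap, ph,
                            labels, meta)
                pops.append((name, pop, phenos))
            for name, pop, phenos in pops:
                _analyse_population(name, pop, phenos, config, out, log)
        log.line("done", "all stages completed")
    finally:
        log.close()
    return out


def _stage_fixtures(config: RunConfig, out: Path, log: _Log):
    try:
        study = poo.classify_study(alpha=config.alpha,
                                   min_phenos=config.min_interaction_phenos,
                                   merge_mb=config.merge_mb)
        _write(study.qtls, out / "poo_classification.tsv", log, "fixtures")
        _write(poo.summarize_poo(study), out / "poo_summary.tsv", log,
               "fixtures")
        val = poo.validate_cross_population(
            study.records[study.records["population"] == "DABC"],
            study.records[study.records["population"] == "PVGBC"])
        _write(val, out / "cross_validation.tsv", log, "fixtures")
        sentences = results_sentences(study)
        (out / "results_sentences.json").write_text(
            json.dumps(sentences, indent=1, sort_keys=True) + "\n")
        log.line("fixtures", "wrote results_sentences.json")
        _write(recompute_table1(), out / "table1_recomputed.tsv", log,
               "fixtures")
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("fixtures", str(e)) from e


def _analyse_population(name: str, pop, phenos: pd.DataFrame,
                        config: RunConfig, out: Path, log: _Log):
    stage = "scan"
    try:
        probs = calc_genoprob(pop.genotype_codes(), pop.gmap,
                              step_mb=config.step_mb,
                              error_prob=config.error_prob)
        thr_rows = []
        for ph in config.phenotypes:
            y = phenos[ph].to_numpy(float)
            res = scan_hk(probs, y, pheno_name=ph)
            _write(res.table, out / f"scan_{name}_{ph}.tsv", log, stage)
            thr = permute_threshold(probs, y, n_perm=config.n_perm,
                                    alpha=config.alpha, seed=config.seed)
            peak = res.max()
            thr_rows.append({
                "population": name, "phenotype": ph,
                "threshold": thr.value, "alpha": config.alpha,
                "n_perm": config.n_perm, "max_lod": peak["lod"],
                "peak_chrom": peak["chrom"], "peak_pos_mb": peak["pos_mb"],
                "significant": peak["lod"] >= thr.value})
        thr_df = pd.DataFrame(thr_rows)
        _write(thr_df, out / f"thresholds_{name}.tsv", log, stage)

        stage = "mqm"
        ph0 = config.phenotypes[0]
        model = forward_backward_select(
            probs, phenos[ph0].to_numpy(float),
            max_qtl=config.max_qtl, keep_lod=config.keep_lod)
        report = [f"multiple-QTL model for {name}/{ph0}"]
        report += list(model.trace)
        if model.qtls:
            imput = sim_geno(pop.genotype_codes(), pop.gmap,
                             n_draws=config.n_imp, step_mb=config.step_mb,
                             error_prob=config.error_prob, seed=config.seed)
            fit = fit_qtl(model, imput, phenos[ph0].to_numpy(float))
            report.append(f"model LOD {fit.lod:.2f}, variance explained "
                          f"{fit.varexp:.1f}%")
            _write(fit.drop_table, out / f"mqm_{name}_{ph0}.tsv", log, stage)
        (out / f"mqm_{name}_{ph0}.txt").write_text("\n".join(report) + "\n")
        log.line(stage, f"{name}/{ph0}: {len(model.qtls)} QTLs retained")

        stage = "poo"
        strat = poo.stratified_scan(
            pop, phenos, pheno_names=config.phenotypes,
            locate_lod=config.locate_lod, detect_alpha=config.detect_alpha,
            merge_mb=config.merge_mb, step_mb=config.step_mb,
            error_prob=config.error_prob)
        for w in strat.warnings:
            log.line(stage, f"warning: {w}")
        det = strat.detections
        _write(det, out / f"poo_detections_{name}.tsv", log, stage)
        if not det.empty:
            popn = _population_of(pop)
            records = poo.detections_to_records(det, popn)
            calls = poo.classify_records(records, merge_mb=config.merge_mb)
            qtl_list = [(r["chrom"], float(r["pos_mb"]))
                        for _, r in det.iterrows()]
            cands = [(r["chrom"], float(r["pos_mb"]))
                     for _, r in det.iterrows()
                     if sum(bool(r[poo.DET_COLS[c]])
                            for c in POPULATIONS[popn]) == 1]
            if cands:
                ip = poo.interaction_test(
                    pop, phenos, qtl_list, cands,
                    pheno_names=("INC",) + tuple(config.phenotypes),
                    n_imp=config.n_imp, step_mb=config.step_mb,
                    error_prob=config.error_prob, seed=config.seed)
                _write(ip.reset_index(),
                       out / f"poo_interactions_{name}.tsv", log, stage)
                npass = (ip <= config.alpha).sum(axis=0)
                calls["interaction_pass"] = [
                    bool(npass.get(f"{c}:{p:g}", 0)
                         >= config.min_interaction_phenos)
                    for c, p in ((r["chrom"], float(r["pos_mb"]))
                                 for _, r in calls.iterrows())]
            _write(calls, out / f"poo_calls_{name}.tsv", log, stage)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, f"{name}: {e}") from e


def _population_of(pop) -> str:
    crosses = set(pop.cross)
    for popn, cs in POPULATIONS.items():
        if crosses <= set(cs):
            return popn
    raise ValueError(f"cross labels {sorted(crosses)} do not form a "
                     "recognized population")
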