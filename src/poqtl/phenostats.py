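"""Clinical phenotype derivation and reciprocal-cross comparison statistics.

Daily 0-5 neurological scores are reduced to the standard EAE phenotypes
(incidence, onset, duration, maximum score, weight loss), and reciprocal
crosses are compared phenotype by phenotype: Fisher's exact test for
incidence, Student's t-test for the continuous phenotypes, with Mann-Whitney
and variance tests (F and Levene) as robustness checks.  The t-test is also
available directly from printed group summaries (mean, SD, n), which allows
published comparison tables to be recomputed without raw data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sd < 0:
            raise ValueError("SD must be >= 0")


@dataclass(frozen=True)
class ClinicalPhenotypes:
    INC: int
    ONS: float
    DUR: float
    MAX: float
    WL: float


def derive_phenotypes(scores: np.ndarray, weights: np.ndarray,
                      weight_at_immunization: float,
                      study_end: int | None = None,
                      censor_onset: str = "study_end") -> ClinicalPhenotypes:
    """Reduce a daily score/weight series to clinical phenotypes.

    Scoring starts at day 7 post immunization.  An animal is affected
    (INC = 1) only if signs were present on more than one day; onset is the
    first scored day, duration the number of scored days, MAX the maximum
    score, and WL the largest weight loss as a percentage of the weight at
    immunization.  Unaffected animals get the censor policy onset (study
    end by default), zero duration and zero maximum score.
    """
    s = np.asarray(scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    if s.size == 0:
        raise ValueError("need at least one scored day")
    if not set(np.unique(s[np.isfinite(s)])).issubset({0, 1, 2, 3, 4, 5}):
        raise ValueError("scores must be on the 0-5 scale")
    if weight_at_immunization <= 0 or np.any(w <= 0):
        raise ValueError("weights must be positive")
    days = 7 + np.arange(s.size)
    end = int(study_end if study_end is not None else days[-1])
    sick = s > 0
    n_sick_days = int(sick.sum())
    inc = int(n_sick_days > 1)       # signs on more than one day
    if inc:
        ons = float(days[np.argmax(sick)])
        dur = float(n_sick_days)
        mx = float(s.max())
    else:
        ons = np.nan if censor_onset == "nan" else float(end)
        dur, mx = 0.0, 0.0
    wl = 100.0 * (weight_at_immunization - float(w.min())) / weight_at_immunization
    return ClinicalPhenotypes(INC=inc, ONS=ons, DUR=dur, MAX=mx, WL=wl)


def ttest_from_summary(g1: GroupSummary, g2: GroupSummary,
                       variant: str = "pooled") -> tuple[float, float, float]:
    """Two-sample t-test from group summary statistics.

    Returns (t, df, two-sided p).  The pooled-variance Student form is the
    default; Welch's unequal-variance form is also available.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    if g1.sd == 0 and g2.sd == 0:
        if g1.mean == g2.mean:
            return 0.0, float(g1.n + g2.n - 2), 1.0
        raise ValueError("zero variance with unequal means")
    res = stats.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n,
        equal_var=(variant == "pooled"))
    if variant == "pooled":
        df = float(g1.n + g2.n - 2)
    else:
        v1, v2 = g1.sd ** 2 / g1.n, g2.sd ** 2 / g2.n
        df = (v1 + v2) ** 2 / (v1 ** 2 / (g1.n - 1) + v2 ** 2 / (g2.n - 1))
    return float(res.statistic), df, float(res.pvalue)


def fisher_incidence(affected1: int, n1: int, affected2: int, n2: int) -> float:
    """Two-sided Fisher's exact p for an incidence difference."""
    for a, n in ((affected1, n1), (affected2, n2)):
        if a < 0 or n <= 0 or a > n:
            raise ValueError("invalid incidence counts")
    table = [[affected1, n1 - affected1], [affected2, n2 - affected2]]
    if affected1 + affected2 == 0 or (n1 - affected1) + (n2 - affected2) == 0:
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def robustness_tests(values1, values2) -> dict:
    """Nonparametric and variance-homogeneity checks for a two-group
    comparison: Mann-Whitney U, two-variance F test, Brown-Forsythe Levene
    (absolute deviations from the median)."""
    x = np.asarray(values1, dtype=float)
    y = np.asarray(values2, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need at least 3 values per group")
    if np.std(np.concatenate([x, y])) == 0:
        mw = 1.0
    else:
        mw = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    v1, v2 = np.var(x, ddof=1), np.var(y, ddof=1)
    if v1 == 0 and v2 == 0:
        f_p = 1.0
    else:
        F = v1 / v2 if v2 > 0 else np.inf
        p_one = stats.f.sf(F, len(x) - 1, len(y) - 1)
        f_p = float(min(1.0, 2 * min(p_one, 1 - p_one)))
    if v1 == 0 and v2 == 0:
        lev = 1.0
    else:
        lev = float(stats.levene(x, y, center="median").pvalue)
    return {"mannwhitney_p": mw, "ftest_p": f_p, "levene_p": lev}


CONTINUOUS_PHENOS = ("weight", "MAX", "DUR", "ONS", "WL")


def compare_reciprocal(phenotypes: pd.DataFrame, cross_a: str, cross_b: str,
                       by_sex: bool = True) -> pd.DataFrame:
    """Reciprocal-cross comparison table.

    One row per phenotype (and sex stratum): group means/SDs/n for each
    cross, the test used (Fisher for incidence, pooled t otherwise) and its
    two-sided p-value.
    """
    for c in (cross_a, cross_b):
        if not (phenotypes["cross"] == c).any():
            raise ValueError(f"cross {c!r} absent from phenotype table")
    strata = [("F",), ("M",)] if by_sex else [tuple(phenotypes["sex"].unique())]
    rows = []
    for sexes in strata:
        sub = phenotypes[phenotypes["sex"].isin(sexes)]
        a = sub[sub["cross"] == cross_a]
        b = sub[sub["cross"] == cross_b]
        label = "+".join(sexes)
        inc_p = fisher_incidence(int(a["INC"].sum()), len(a),
                                 int(b["INC"].sum()), len(b))
        rows.append((label, "INC", a["INC"].mean(), a["INC"].std(ddof=1),
                     len(a), b["INC"].mean(), b["INC"].std(ddof=1), len(b),
                     "fisher", inc_p))
        for ph in CONTINUOUS_PHENOS:
            if ph not in sub.columns:
                continue
            xa = a[ph].to_numpy(float)
            xb = b[ph].to_numpy(float)
            xa, xb = xa[np.isfinite(xa)], xb[np.isfinite(xb)]
            ga = GroupSummary(xa.mean(), xa.std(ddof=1), len(xa))
            gb = GroupSummary(xb.mean(), xb.std(ddof=1), len(xb))
            _, _, p = ttest_from_summary(ga, gb)
            rows.append((label, ph, ga.mean, ga.sd, ga.n,
                         gb.mean, gb.sd, gb.n, "t", p))
    return pd.DataFrame(rows, columns=[
        "sex", "phenotype", f"mean_{cross_a}", f"sd_{cross_a}", f"n_{cross_a}",
        f"mean_{cross_b}", f"sd_{cross_b}", f"n_{cross_b}", "test", "p"])
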