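"""Bundled transcriptions of the published summary tables.

No raw genotype or phenotype data were deposited for the reciprocal
backcross study, but its printed summary tables are inputs in their own
right: per-QTL per-cross significance calls, cross-by-QTL and origin-by-QTL
interaction p-values, and reciprocal-cross group summaries.  These loaders
return them as tidy DataFrames for the classification and summary machinery
in :mod:`poqtl.poo` and :mod:`poqtl.phenostats`.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

_PHENO_COLS = ("ons", "max", "wl")


def _read(name: str) -> pd.DataFrame:
    with resources.files("poqtl.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#", dtype=str)


def _numeric_p(df: pd.DataFrame, cols) -> pd.DataFrame:
    for c in cols:
        df[c] = pd.to_numeric(df[c].replace({"ns": np.nan, "NA": np.nan}),
                              errors="raise")
    return df


def load_qtl_effects(population: str) -> pd.DataFrame:
    """Per-QTL allelic-effect calls for 'DABC' or 'PVGBC'.

    Columns: qtl, sex, chrom, pos_mb, shared, per-cross ONS/MAX/WL p-values
    (NaN where not significant), allele, cross (identifying cross, ALL, or
    POP for whole-population-only QTLs) and the published transmission call.
    """
    population = population.upper()
    if population == "DABC":
        df = _read("dabc_qtl_effects.tsv")
        crosses = ("daxf1", "f1xda")
    elif population == "PVGBC":
        df = _read("pvgbc_qtl_effects.tsv")
        crosses = ("pvgxf1", "f1xpvg")
    else:
        raise ValueError("population must be 'DABC' or 'PVGBC'")
    pcols = [f"{p}_pop" for p in _PHENO_COLS]
    pcols += [f"{p}_{c}" for c in crosses for p in _PHENO_COLS]
    df = _numeric_p(df, pcols)
    df["pos_mb"] = df["pos_mb"].astype(float)
    df["population"] = population
    df["trans"] = df["trans"].replace({".": ""})
    return df


def load_interactions() -> pd.DataFrame:
    """Cross-by-QTL interaction p-values for the ten single-cross candidates."""
    df = _read("cross_by_qtl_interactions.tsv")
    return _numeric_p(df, ["inc", "max", "dur", "ons", "wl"])


def load_g10_interactions() -> pd.DataFrame:
    """Origin-by-QTL interaction p-values from the G10 advanced intercross."""
    df = _read("g10_origin_interactions.tsv")
    return _numeric_p(df, ["inc", "max", "dur", "ons", "wl"])


def load_reciprocal_summaries() -> pd.DataFrame:
    """Published group summaries (mean, SD, n) for the DABC comparison."""
    df = _read("reciprocal_summaries.tsv")
    for c in ("mean", "sd"):
        df[c] = df[c].astype(float)
    df["n"] = df["n"].astype(int)
    return df
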