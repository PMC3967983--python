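"""Cross files, pedigree sidecars and run configuration.

One cross-file dialect is supported: a comma-separated table whose leading
comment lines carry ``#key=value`` metadata, followed by three header rows
(column names; chromosome of each marker column; genetic position in cM) and
one row per individual.  Phenotype and label columns come first, then marker
columns with genotype codes ``A`` (homozygous recurrent), ``H``
(heterozygous) and ``-`` (missing).  Physical positions are recovered from
the ``cm_per_mb`` metadata rate, which is stored on write so files
round-trip bit-exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genmap import DEFAULT_CM_PER_MB, GeneticMap
from .genoprob import HET, HOM, MISSING

CODE_TO_INT = {"A": HOM, "H": HET, "-": MISSING}
INT_TO_CODE = {v: k for k, v in CODE_TO_INT.items()}

#: non-marker columns recognized in the leading block
LABEL_COLS = ("id", "cross", "sex")


@dataclass
class CrossData:
    """Contents of a cross file."""

    genotypes: np.ndarray          # (n, markers) int8 codes 0/1/-1
    gmap: GeneticMap
    phenos: pd.DataFrame           # phenotype columns, one row per individual
    labels: pd.DataFrame           # id, cross, sex
    metadata: dict

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]


def write_cross(path: str | Path, genotypes: np.ndarray, gmap: GeneticMap,
                phenos: pd.DataFrame, labels: pd.DataFrame,
                metadata: dict | None = None) -> None:
    """Write a cross file (see module docstring for the dialect)."""
    path = Path(path)
    genotypes = np.asarray(genotypes)
    n, m = genotypes.shape
    if m != gmap.n_markers:
        raise ValueError(f"genotypes have {m} columns but map has "
                         f"{gmap.n_markers} markers")
    if len(phenos) != n or len(labels) != n:
        raise ValueError("phenotype/label row count does not match genotypes")
    meta = dict(metadata or {})
    meta.setdefault("cm_per_mb", repr(gmap.cm_per_mb))
    lead = [c for c in LABEL_COLS if c in labels.columns]
    lead += [c for c in phenos.columns]
    markers = gmap.marker_names
    with path.open("w") as fh:
        for k, v in meta.items():
            fh.write(f"#{k}={v}\n")
        fh.write(",".join(lead + markers) + "\n")
        blanks = [""] * len(lead)
        fh.write(",".join(blanks + [str(c) for c in gmap.table["chrom"]])
                 + "\n")
        fh.write(",".join(blanks + [repr(float(p))
                                    for p in gmap.table["pos_cm"]]) + "\n")
        for i in range(n):
            cells = []
            for c in lead:
                src = labels if c in labels.columns else phenos
                v = src[c].iloc[i]
                cells.append("" if pd.isna(v) else str(v))
            cells += [INT_TO_CODE[int(g)] for g in genotypes[i]]
            fh.write(",".join(cells) + "\n")


def read_cross(path: str | Path) -> CrossData:
    """Read a cross file written by :func:`write_cross`.

    Raises ``ValueError`` naming the individual row and marker column for
    any genotype code outside ``{A, H, -}``, and on duplicate marker names.
    """
    path = Path(path)
    meta: dict = {}
    with path.open() as fh:
        lines = fh.read().splitlines()
    body = []
    for ln in lines:
        if ln.startswith("#"):
            k, _, v = ln[1:].partition("=")
            meta[k.strip()] = v.strip()
        elif ln.strip():
            body.append(ln)
    if len(body) < 3:
        raise ValueError(f"{path}: malformed cross file (needs three "
                         "header rows)")
    names = body[0].split(",")
    chroms = body[1].split(",")
    cms = body[2].split(",")
    if not (len(names) == len(chroms) == len(cms)):
        raise ValueError(f"{path}: header rows have inconsistent column "
                         "counts")
    # marker columns are those with a chromosome entry
    is_marker = [c.strip() != "" for c in chroms]
    lead = [nm for nm, m in zip(names, is_marker) if not m]
    markers = [nm for nm, m in zip(names, is_marker) if m]
    if "cross" not in lead or "sex" not in lead:
        raise ValueError(f"{path}: every individual needs a cross label and "
                         "sex; add 'cross' and 'sex' columns")
    seen = set()
    for nm in markers:
        if nm in seen:
            raise ValueError(f"{path}: duplicate marker name {nm!r}")
        seen.add(nm)
    cm_per_mb = float(meta.get("cm_per_mb", DEFAULT_CM_PER_MB))
    pos_cm = [float(c) for c, m in zip(cms, is_marker) if m]
    chrom_col = [c for c, m in zip(chroms, is_marker) if m]
    gmap = GeneticMap(pd.DataFrame({
        "marker": markers, "chrom": chrom_col, "pos_cm": pos_cm,
        "pos_mb": [c / cm_per_mb for c in pos_cm]}), cm_per_mb=cm_per_mb)

    n_lead = len(lead)
    n = len(body) - 3
    geno = np.empty((n, len(markers)), dtype=np.int8)
    lead_rows = []
    for i, ln in enumerate(body[3:]):
        cells = ln.split(",")
        if len(cells) != len(names):
            raise ValueError(f"{path}: row {i + 1} has {len(cells)} cells, "
                             f"expected {len(names)}")
        lead_rows.append(cells[:n_lead])
        for j, cell in enumerate(cells[n_lead:]):
            code = cell.strip()
            if code not in CODE_TO_INT:
                ind = cells[lead.index("id")] if "id" in lead else str(i + 1)
                raise ValueError(
                    f"{path}: invalid genotype code {code!r} for individual "
                    f"{ind} (row {i + 1}) at marker {markers[j]} "
                    f"(column {n_lead + j + 1})")
            geno[i, j] = CODE_TO_INT[code]
    lead_df = pd.DataFrame(lead_rows, columns=lead)
    labels = lead_df[[c for c in LABEL_COLS if c in lead]].copy()
    pheno_cols = [c for c in lead if c not in LABEL_COLS]

    def _exact_float(cell: str) -> float:
        # Python's float() is correctly rounded, so written values
        # round-trip bit-exactly (pandas' fast parser is off by 1 ulp).
        try:
            return float(cell)
        except ValueError:
            return np.nan

    phenos = lead_df[pheno_cols].map(_exact_float)
    return CrossData(genotypes=geno, gmap=gmap, phenos=phenos,
                     labels=labels, metadata=meta)


def population_to_cross_data(pop, phenos: pd.DataFrame,
                             error_prob: float = 0.0,
                             missing_prob: float = 0.0,
                             rng=None, metadata: dict | None = None):
    """Assemble write_cross arguments from a simulated population."""
    labels = pd.DataFrame({
        "id": pop.ids,
        "cross": pop.cross,
        "sex": np.where(np.asarray(pop.sex) == 1, "M", "F"),
    })
    pheno_only = phenos[[c for c in phenos.columns
                         if c not in ("sex", "cross")]]
    geno = pop.genotype_codes(error_prob=error_prob,
                              missing_prob=missing_prob, rng=rng)
    meta = dict(metadata or {})
    if pop.seed is not None:
        meta.setdefault("seed", str(pop.seed))
    return geno, pop.gmap, pheno_only, labels, meta


def write_pedigree(path: str | Path, pedigree: pd.DataFrame) -> None:
    """Write a pedigree sidecar (tab-separated)."""
    pedigree.to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """All tunable parameters of the pipeline, serialized with every output.

    Defaults match the module-level defaults of the analysis functions.
    """

    seed: int = 0
    step_mb: float = 1.0
    error_prob: float = 1e-4
    n_perm: int = 1000
    alpha: float = 0.05
    max_qtl: int = 10
    keep_lod: float = 1.5
    n_imp: int = 128
    merge_mb: float = 20.0
    min_interaction_phenos: int = 2
    censor_onset: str = "study_end"
    locate_lod: float = 1.3
    detect_alpha: float = 0.05
    phenotypes: tuple = ("ONS", "MAX", "WL")
    simulate: dict | None = None      # optional simulation recipe

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phenotypes"] = list(d["phenotypes"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "phenotypes" in d:
            d = {**d, "phenotypes": tuple(d["phenotypes"])}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
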