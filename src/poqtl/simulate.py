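"""Simulation of reciprocal backcross and advanced-intercross populations.

The simulator emulates the breeding design used to detect parent-of-origin
effects in rat EAE: two backcross populations (DABC on the susceptible DA
background, PVGBC on the resistant PVG background), each made of two
reciprocal crosses in which the same segregating allele is inherited either
maternally or paternally, plus a 10-generation advanced intercross (AIL)
with recorded G9 family origin.

Alleles carry an explicit strain (D = DA, P = PVG) and an implicit origin
tag: each individual's genome is stored as a maternal haplotype array and a
paternal haplotype array, so exactly one allele per locus is maternal and
one paternal by construction.  Meiosis re-tags transmitted alleles simply by
which array of the offspring the gamete is written into.

Genetic effects on the disease liability can be additive, expressed only
from the maternal or the paternal copy (imprinting-like), Y-linked (males
only, following the patriline strain) or mitochondrial (expressed only in
individuals whose mitochondrial lineage carries the risk strain).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genmap import GeneticMap, haldane

D, P = 0, 1
STRAIN_CODE = {"D": D, "P": P}
STRAIN_NAME = {D: "D", P: "P"}

BACKCROSS_LABELS = ("DAxF1", "F1xDA", "PVGxF1", "F1xPVG")
AIL_LABEL = "AIL_G10"

MODES = ("additive", "maternal_expressed", "paternal_expressed",
         "y_linked", "mitochondrial")


def substream(seed: int, name: str) -> np.random.Generator:
    """Named RNG substream derived from a single root seed.

    Uses a CRC32 of the stream name so the mapping is stable across
    processes (unlike the builtin ``hash``).
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


# ---------------------------------------------------------------------------
# cross designs


@dataclass(frozen=True)
class CrossDesign:
    """One of the four reciprocal backcrosses (mother x father).

    The mitochondrial strain follows the maternal lineage founder and the Y
    strain follows the patriline founder; in this design the F1 generation
    always derives from a DA mother and a PVG father, so F1 mothers
    contribute DA mitochondria and F1 fathers contribute the PVG Y.
    """

    label: str
    mother: str  # "DA", "PVG" or "F1"
    father: str
    mito_strain: int
    y_strain: int

    @property
    def recurrent_strain(self) -> int:
        """Strain of the inbred (recurrent) parent."""
        inbred = self.mother if self.mother != "F1" else self.father
        return D if inbred == "DA" else P

    @property
    def f1_parent_sex(self) -> str:
        """'mother' if the F1 hybrid is the dam, else 'father'."""
        return "mother" if self.mother == "F1" else "father"


_DESIGNS = {
    "DAxF1": CrossDesign("DAxF1", "DA", "F1", mito_strain=D, y_strain=P),
    "F1xDA": CrossDesign("F1xDA", "F1", "DA", mito_strain=D, y_strain=D),
    "PVGxF1": CrossDesign("PVGxF1", "PVG", "F1", mito_strain=P, y_strain=P),
    "F1xPVG": CrossDesign("F1xPVG", "F1", "PVG", mito_strain=D, y_strain=P),
}

#: crosses in which the F1 hybrid is the mother (segregating allele is
#: maternally inherited) and the father (paternally inherited)
F1_MOTHER_CROSSES = ("F1xDA", "F1xPVG")
F1_FATHER_CROSSES = ("DAxF1", "PVGxF1")

POPULATIONS = {"DABC": ("DAxF1", "F1xDA"), "PVGBC": ("PVGxF1", "F1xPVG")}


def cross_design(label: str) -> CrossDesign:
    try:
        return _DESIGNS[label]
    except KeyError:
        raise ValueError(
            f"unknown cross label {label!r}; expected one of {BACKCROSS_LABELS}"
        ) from None


# ---------------------------------------------------------------------------
# QTL specification


@dataclass(frozen=True)
class QTLSpec:
    """A simulated genetic effect on the disease liability.

    ``effect`` is on the standardized liability scale (per risk allele for
    the additive mode, per expressed risk allele otherwise).
    """

    chrom: str
    pos_mb: float
    mode: str
    effect: float
    risk_strain: str = "P"

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown QTL mode {self.mode!r}")
        if not np.isfinite(self.effect):
            raise ValueError("QTL effect must be finite")
        if self.risk_strain not in STRAIN_CODE:
            raise ValueError("risk_strain must be 'D' or 'P'")


# ---------------------------------------------------------------------------
# populations


@dataclass
class SimPopulation:
    """A simulated cross: allele-pair genomes with parental-origin tags.

    ``maternal[i, j]`` / ``paternal[i, j]`` hold the strain (0 = DA, 1 =
    PVG) of the maternally / paternally inherited allele of individual ``i``
    at marker ``j`` (columns follow ``gmap.table`` order).
    """

    gmap: GeneticMap
    maternal: np.ndarray
    paternal: np.ndarray
    sex: np.ndarray          # 0 = female, 1 = male
    cross: np.ndarray        # per-individual cross label
    mito: np.ndarray         # per-individual mitochondrial strain
    y: np.ndarray            # per-individual patriline Y strain
    seed: int | None = None
    recurrent: np.ndarray | None = None   # per-individual recurrent strain, -1 if n/a
    origin: np.ndarray | None = None      # AIL G9 family label
    pedigree: pd.DataFrame | None = None
    ids: np.ndarray = field(default=None)

    def __post_init__(self):
        n = self.maternal.shape[0]
        if self.ids is None:
            self.ids = np.arange(1, n + 1)
        if self.recurrent is None:
            self.recurrent = np.full(n, -1, dtype=np.int8)

    @property
    def n(self) -> int:
        return self.maternal.shape[0]

    @property
    def n_markers(self) -> int:
        return self.maternal.shape[1]

    def het(self) -> np.ndarray:
        """Heterozygosity indicator (n x markers)."""
        return (self.maternal != self.paternal).astype(np.int8)

    def dosage(self, strain: str) -> np.ndarray:
        """Allele count of a founder strain at every marker."""
        s = STRAIN_CODE[strain]
        return ((self.maternal == s).astype(np.int8)
                + (self.paternal == s).astype(np.int8))

    def genotype_codes(self, error_prob: float = 0.0,
                       missing_prob: float = 0.0,
                       rng: np.random.Generator | None = None) -> np.ndarray:
        """Observed backcross genotype matrix: 0 = hom recurrent, 1 = het,
        -1 = missing; optional symmetric misclassification noise."""
        g = self.het().astype(np.int8)
        if error_prob > 0 or missing_prob > 0:
            if rng is None:
                rng = np.random.default_rng(0)
            if error_prob > 0:
                flip = rng.random(g.shape) < error_prob
                g = np.where(flip, 1 - g, g).astype(np.int8)
            if missing_prob > 0:
                g[rng.random(g.shape) < missing_prob] = -1
        return g

    def subset(self, mask: np.ndarray) -> "SimPopulation":
        idx = np.asarray(mask)
        return SimPopulation(
            gmap=self.gmap,
            maternal=self.maternal[idx],
            paternal=self.paternal[idx],
            sex=self.sex[idx],
            cross=self.cross[idx],
            mito=self.mito[idx],
            y=self.y[idx],
            seed=self.seed,
            recurrent=self.recurrent[idx],
            origin=None if self.origin is None else self.origin[idx],
            ids=self.ids[idx],
        )


def combine(pops: list[SimPopulation]) -> SimPopulation:
    """Stack populations sharing the same map (e.g. two reciprocal crosses)."""
    first = pops[0]
    for p in pops[1:]:
        if p.gmap.marker_names != first.gmap.marker_names:
            raise ValueError("populations use different maps")
    cat = lambda attr: np.concatenate([getattr(p, attr) for p in pops])
    origin = (None if any(p.origin is None for p in pops)
              else np.concatenate([p.origin for p in pops]))
    return SimPopulation(
        gmap=first.gmap,
        maternal=cat("maternal"), paternal=cat("paternal"),
        sex=cat("sex"), cross=cat("cross"), mito=cat("mito"), y=cat("y"),
        seed=first.seed, recurrent=cat("recurrent"), origin=origin,
        ids=np.arange(1, sum(p.n for p in pops) + 1),
    )


# ---------------------------------------------------------------------------
# meiosis


def _meiosis_batch(hap_a: np.ndarray, hap_b: np.ndarray, gmap: GeneticMap,
                   rng: np.random.Generator) -> np.ndarray:
    """Sample one gamete per row from a batch of parental genomes.

    Crossovers follow a Markov chain along each chromosome with Haldane
    recombination fractions between adjacent markers (no interference).
    """
    n, m = hap_a.shape
    gam = np.empty((n, m), dtype=np.int8)
    col = 0
    for chrom in gmap.chromosomes:
        cm = gmap.positions_cm(chrom)
        k = len(cm)
        r = haldane(np.diff(cm))
        # phase[:, j] == 0 -> copy from hap_a at marker j
        switch = rng.random((n, k - 1)) < r
        start = rng.integers(0, 2, size=(n, 1), dtype=np.int8)
        phase = np.concatenate(
            [start, np.bitwise_xor.accumulate(switch, axis=1) ^ start], axis=1
        ).astype(bool)
        block_a = hap_a[:, col:col + k]
        block_b = hap_b[:, col:col + k]
        gam[:, col:col + k] = np.where(phase, block_b, block_a)
        col += k
    return gam


def simulate_meiosis(parent_maternal: np.ndarray, parent_paternal: np.ndarray,
                     gmap: GeneticMap, rng: np.random.Generator) -> np.ndarray:
    """Sample a single gamete from one parent's allele-pair genome.

    The returned array carries one allele strain per marker; its origin tag
    in the offspring is set by the transmitting parent's sex (it becomes the
    offspring's maternal haplotype if the parent is the dam).
    """
    a = np.atleast_2d(np.asarray(parent_maternal, dtype=np.int8))
    b = np.atleast_2d(np.asarray(parent_paternal, dtype=np.int8))
    if a.shape[1] != gmap.n_markers:
        raise ValueError("parent genome does not match the map")
    return _meiosis_batch(a, b, gmap, rng)[0]


def _founder(strain: int, n: int, m: int) -> tuple[np.ndarray, np.ndarray]:
    h = np.full((n, m), strain, dtype=np.int8)
    return h, h.copy()


def _f1_genome(n: int, m: int) -> tuple[np.ndarray, np.ndarray]:
    # F1 from DA mother x PVG father: maternal haplotype D, paternal P
    return (np.full((n, m), D, dtype=np.int8), np.full((n, m), P, dtype=np.int8))


def breed_backcross(design: CrossDesign | str, n: int, gmap: GeneticMap,
                    seed: int = 0) -> SimPopulation:
    """Simulate offspring of one reciprocal backcross.

    Each offspring receives a maternal gamete from the dam and a paternal
    gamete from the sire; the inbred parent contributes a non-segregating
    haplotype, so heterozygosity at any autosomal locus has expectation 0.5.
    """
    if isinstance(design, str):
        if design == AIL_LABEL:
            raise ValueError("use breed_ail for the advanced intercross")
        design = cross_design(design)
    if n < 1:
        raise ValueError("n must be >= 1")
    m = gmap.n_markers
    rng = substream(seed, f"backcross:{design.label}")

    def parent_genome(which: str):
        if which == "F1":
            return _f1_genome(n, m)
        return _founder(D if which == "DA" else P, n, m)

    mom_a, mom_b = parent_genome(design.mother)
    dad_a, dad_b = parent_genome(design.father)
    maternal = _meiosis_batch(mom_a, mom_b, gmap, rng)
    paternal = _meiosis_batch(dad_a, dad_b, gmap, rng)
    sex = rng.integers(0, 2, size=n, dtype=np.int8)
    return SimPopulation(
        gmap=gmap, maternal=maternal, paternal=paternal, sex=sex,
        cross=np.full(n, design.label, dtype=object),
        mito=np.full(n, design.mito_strain, dtype=np.int8),
        y=np.full(n, design.y_strain, dtype=np.int8),
        seed=seed,
        recurrent=np.full(n, design.recurrent_strain, dtype=np.int8),
    )


def breed_ail(n_founders_per_sex: int, generations: int = 10,
              n_final: int = 200, gmap: GeneticMap = None,
              seed: int = 0, founder_strains: tuple[str, str] = ("D", "P"),
              ) -> SimPopulation:
    """Simulate an advanced intercross line by random non-sib mating.

    Generation 1 is the F1 of the two founder strains; each subsequent
    generation pairs males and females at random while avoiding
    brother-sister matings.  Individuals of the final generation record the
    family (breeding pair) of their parents in the previous generation,
    which serves as the 'origin' covariate for G10 analyses.
    """
    if generations < 2:
        raise ValueError("need at least 2 generations (F2)")
    if n_founders_per_sex < 2:
        raise ValueError("need at least 2 breeding pairs per generation")
    if gmap is None:
        raise ValueError("a genetic map is required")
    rng = substream(seed, "ail")
    m = gmap.n_markers
    k = n_founders_per_sex
    s0, s1 = STRAIN_CODE[founder_strains[0]], STRAIN_CODE[founder_strains[1]]

    # generation 1: F1 hybrids (maternal haplotype from strain-0 dam)
    def f1(n):
        return (np.full((n, m), s0, dtype=np.int8),
                np.full((n, m), s1, dtype=np.int8))

    fem_mat, fem_pat = f1(k)
    mal_mat, mal_pat = f1(k)
    fem_fam = np.arange(k)      # family = breeding pair of the parents
    mal_fam = np.arange(k)
    pedigree_rows = []

    for gen in range(2, generations + 1):
        final = gen == generations
        n_off = n_final if final else 2 * k
        # pair every male with a non-sib female (random derangement search)
        order = rng.permutation(k)
        for _ in range(100):
            if not np.any(fem_fam == mal_fam[order]):
                break
            order = rng.permutation(k)
        else:
            # deterministic fallback: shift males by one family
            order = np.argsort((mal_fam + 1) % k, kind="stable")
        pair_mother = rng.integers(0, k, size=n_off)
        mothers = pair_mother
        fathers = order[pair_mother]
        off_mat = _meiosis_batch(fem_mat[mothers], fem_pat[mothers], gmap, rng)
        off_pat = _meiosis_batch(mal_mat[fathers], mal_pat[fathers], gmap, rng)
        off_sex = rng.integers(0, 2, size=n_off, dtype=np.int8)
        off_fam = pair_mother.copy()   # breeding-pair label
        for i in range(n_off):
            pedigree_rows.append((gen, i + 1, mothers[i] + 1, fathers[i] + 1,
                                  "F" if off_sex[i] == 0 else "M"))
        if final:
            return SimPopulation(
                gmap=gmap, maternal=off_mat, paternal=off_pat, sex=off_sex,
                cross=np.full(n_off, AIL_LABEL, dtype=object),
                mito=np.full(n_off, s0, dtype=np.int8),
                y=np.full(n_off, s1, dtype=np.int8),
                seed=seed, origin=off_fam,
                pedigree=pd.DataFrame(
                    pedigree_rows,
                    columns=["generation", "id", "mother", "father", "sex"]),
            )
        # next breeding generation: first k females, first k males
        fem_idx = np.flatnonzero(off_sex == 0)
        mal_idx = np.flatnonzero(off_sex == 1)
        # top up by resampling if a sex is short (small-n edge case)
        while len(fem_idx) < k:
            fem_idx = np.concatenate([fem_idx, fem_idx[: k - len(fem_idx)]])
        while len(mal_idx) < k:
            mal_idx = np.concatenate([mal_idx, mal_idx[: k - len(mal_idx)]])
        fem_idx, mal_idx = fem_idx[:k], mal_idx[:k]
        fem_mat, fem_pat = off_mat[fem_idx], off_pat[fem_idx]
        mal_mat, mal_pat = off_mat[mal_idx], off_pat[mal_idx]
        fem_fam, mal_fam = off_fam[fem_idx], off_fam[mal_idx]
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# phenotypes


@dataclass(frozen=True)
class PhenotypeModelParams:
    """Liability-threshold model for EAE-like clinical phenotypes.

    Disease liability is Gaussian; an animal is affected (INC = 1) when its
    liability exceeds ``incidence_threshold``.  Affected animals receive
    onset, duration and maximum-score values monotone in liability; weight
    loss is observed for every animal.  Link coefficients are chosen so the
    simulated means and dispersions resemble the published reciprocal-cross
    summary tables for MOG-EAE backcrosses (overall MAX near 2 with SD
    around 1.5, duration near 12-16 days, weight-loss SD near 12%).
    """

    intercept: float = 0.0
    residual_sd: float = 1.0
    sex_effect: float = 0.0            # added to male liability
    incidence_threshold: float = 0.0
    study_end: int = 40
    onset_base: float = 18.0
    onset_slope: float = 4.0
    onset_sd: float = 3.0
    max_base: float = 2.2
    max_slope: float = 1.4
    max_sd: float = 0.7
    dur_slope: float = 6.0
    dur_sd: float = 4.0
    wl_base: float = 5.0
    wl_slope: float = 10.0
    wl_sd: float = 5.0
    set_sd: float = 0.1                # additive experimental-set shift
    n_sets: int = 4
    weight_female: tuple = (106.0, 12.0)
    weight_male: tuple = (170.0, 22.0)
    censor_onset: str = "study_end"    # or "nan"

    def expected_incidence(self) -> float:
        """Closed-form incidence with all genetic effects at zero."""
        from scipy.stats import norm
        return float(norm.sf(self.incidence_threshold - self.intercept,
                             scale=self.residual_sd))


def _nearest_marker_column(gmap: GeneticMap, chrom: str, pos_mb: float) -> int:
    if not gmap.contains(chrom, pos_mb):
        raise ValueError(f"QTL at {chrom}:{pos_mb} Mb is off the map")
    offset = 0
    for c in gmap.chromosomes:
        mb = gmap.positions_mb(c)
        if c == str(chrom):
            return offset + int(np.argmin(np.abs(mb - pos_mb)))
        offset += len(mb)
    raise AssertionError("unreachable")


def liability(pop: SimPopulation, qtls: list[QTLSpec],
              params: PhenotypeModelParams, rng: np.random.Generator,
              ) -> np.ndarray:
    """Genetic + environmental disease liability for each individual."""
    lia = np.full(pop.n, params.intercept, dtype=float)
    lia += params.sex_effect * (pop.sex == 1)
    for q in qtls:
        s = STRAIN_CODE[q.risk_strain]
        if q.mode == "y_linked":
            lia += q.effect * ((pop.y == s) & (pop.sex == 1))
            continue
        col = _nearest_marker_column(pop.gmap, q.chrom, q.pos_mb)
        mat = pop.maternal[:, col] == s
        pat = pop.paternal[:, col] == s
        if q.mode == "additive":
            lia += q.effect * (mat.astype(float) + pat)
        elif q.mode == "maternal_expressed":
            lia += q.effect * mat
        elif q.mode == "paternal_expressed":
            lia += q.effect * pat
        elif q.mode == "mitochondrial":
            # nuclear locus expressed only on the risk mitochondrial lineage
            lia += q.effect * (mat.astype(float) + pat) * (pop.mito == s)
    lia += rng.normal(0.0, params.residual_sd, size=pop.n)
    return lia


def simulate_phenotypes(pop: SimPopulation, qtls: list[QTLSpec],
                        params: PhenotypeModelParams | None = None,
                        seed: int = 0) -> pd.DataFrame:
    """EAE-like clinical phenotypes driven by a liability-threshold model.

    Returns a table with INC, ONS, DUR, MAX, WL, weight, sex, cross and
    experimental set, aligned with the population's individuals.
    """
    if params is None:
        params = PhenotypeModelParams()
    rng = substream(seed, "phenotypes")
    lia = liability(pop, qtls, params, rng)
    excess = lia - params.incidence_threshold
    affected = excess > 0

    sets = rng.integers(0, params.n_sets, size=pop.n)
    set_shift = params.set_sd * (sets - (params.n_sets - 1) / 2.0)
    excess = excess + set_shift

    ons = np.round(np.clip(
        params.onset_base - params.onset_slope * excess
        + rng.normal(0, params.onset_sd, pop.n), 7, params.study_end))
    mx = np.clip(params.max_base + params.max_slope * excess
                 + rng.normal(0, params.max_sd, pop.n), 0.5, 5.0)
    dur = np.clip(params.dur_slope * mx + rng.normal(0, params.dur_sd, pop.n),
                  1.0, params.study_end - 7.0)
    wl = (params.wl_base + params.wl_slope * lia
          + rng.normal(0, params.wl_sd, pop.n))

    censor_ons = np.nan if params.censor_onset == "nan" else float(params.study_end)
    ons = np.where(affected, ons, censor_ons)
    mx = np.where(affected, mx, 0.0)
    dur = np.where(affected, dur, 0.0)

    wmean = np.where(pop.sex == 1, params.weight_male[0], params.weight_female[0])
    wsd = np.where(pop.sex == 1, params.weight_male[1], params.weight_female[1])
    weight = rng.normal(wmean, wsd)

    return pd.DataFrame({
        "INC": affected.astype(int), "ONS": ons, "DUR": dur, "MAX": mx,
        "WL": wl, "weight": weight,
        "sex": np.where(pop.sex == 1, "M", "F"),
        "cross": pop.cross, "set": sets + 1,
    })


# ---------------------------------------------------------------------------
# power


def effect_from_varexp(varexp: float) -> float:
    """Backcross allele-substitution effect (in residual SDs) that explains
    a given fraction of phenotypic variance."""
    if not 0 <= varexp < 1:
        raise ValueError("variance explained must be in [0, 1)")
    return 2.0 * np.sqrt(varexp / (1.0 - varexp))


def power_by_simulation(effect: float, n: int, n_sim: int = 5000,
                        threshold_lod: float = 2.7,
                        gmap: GeneticMap | None = None,
                        chrom: str | None = None,
                        qtl_pos_mb: float | None = None,
                        residual_sd: float = 1.0,
                        seed: int = 0) -> tuple[float, float]:
    """QTL detection power for a backcross, estimated by simulation.

    Simulates ``n_sim`` single-QTL backcross populations with a Gaussian
    phenotype (allele-substitution effect in units of ``residual_sd``) and
    reports the percentage whose peak LOD on the QTL's chromosome exceeds
    the threshold, with its binomial standard error (both in percent).
    """
    from .genoprob import calc_genoprob
    from .scan import scan_hk

    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    if residual_sd <= 0:
        raise ValueError("residual variance must be positive")
    if gmap is None:
        from .genmap import make_map
        gmap = make_map({"1": 100.0}, {"1": 6})
    chrom = chrom or gmap.chromosomes[0]
    mb = gmap.positions_mb(chrom)
    if qtl_pos_mb is None:
        qtl_pos_mb = float(mb[len(mb) // 2])
    col = _nearest_marker_column(gmap, chrom, qtl_pos_mb)

    rng = substream(seed, "power")
    hits = 0
    for i in range(n_sim):
        pop = breed_backcross("F1xDA", n, gmap,
                              seed=int(rng.integers(0, 2**31 - 1)))
        y = effect * pop.het()[:, col] + rng.normal(0, residual_sd, n)
        probs = calc_genoprob(pop.genotype_codes(), gmap, step_mb=0,
                              error_prob=1e-4)
        res = scan_hk(probs, y)
        if res.table.loc[res.table["chrom"] == chrom, "lod"].max() >= threshold_lod:
            hits += 1
    frac = hits / n_sim
    se = np.sqrt(frac * (1 - frac) / n_sim)
    return 100.0 * frac, 100.0 * se
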