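"""Single-QTL genome scans by Haley-Knott regression.

At every grid position the phenotype is regressed on the conditional
probability of heterozygosity (plus optional covariates); the evidence for
a QTL is the LOD score ``(n/2) * log10(RSS_null / RSS_full)``, where the
null model contains only the covariates.  Genome-wide significance
thresholds come from permutation of the phenotype labels, and QTL peaks are
localized by bootstrap resampling of individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genoprob import GenotypeProbabilities

LN10 = np.log(10.0)


def _design(n: int, addcovar=None) -> np.ndarray:
    cols = [np.ones(n)]
    if addcovar is not None:
        a = np.asarray(addcovar, dtype=float)
        if a.ndim == 1:
            a = a[:, None]
        cols.append(a)
    return np.column_stack(cols)


def _null_projection(X0: np.ndarray):
    """Orthonormal basis of the covariate space; raises on collinearity."""
    q, rmat = np.linalg.qr(X0)
    diag = np.abs(np.diag(rmat))
    if np.any(diag < 1e-10 * max(1.0, diag.max())):
        raise ValueError("collinear covariates in the null model")
    return q


def zscore_by_set(pheno: pd.Series | np.ndarray, sets: np.ndarray) -> np.ndarray:
    """Standardize a phenotype within experimental sets (batch adjustment)."""
    y = np.asarray(pheno, dtype=float)
    out = np.full_like(y, np.nan)
    for s in np.unique(sets):
        m = (sets == s) & np.isfinite(y)
        if m.sum() >= 2 and np.nanstd(y[m]) > 0:
            out[m] = (y[m] - y[m].mean()) / y[m].std(ddof=1)
        else:
            out[m] = 0.0
    return out


@dataclass
class ScanResult:
    """LOD curve over the genome grid for one phenotype."""

    table: pd.DataFrame          # chrom, pos_mb, pos_cm, name, lod
    phenotype: str
    n: int
    df_covar: int = 0            # covariate columns beyond the intercept
    covariates: str = ""

    def max(self, chrom: str | None = None) -> pd.Series:
        """Peak row; ties broken by the leftmost position."""
        t = self.table if chrom is None else self.table[
            self.table["chrom"] == str(chrom)]
        lod = t["lod"].to_numpy()
        return t.iloc[int(np.argmax(lod))]   # argmax returns first maximum

    def lod_at(self, chrom: str, pos_mb: float) -> float:
        t = self.table[self.table["chrom"] == str(chrom)]
        mb = t["pos_mb"].to_numpy()
        return float(t["lod"].to_numpy()[np.argmin(np.abs(mb - pos_mb))])

    def pointwise_p(self, lod: float | np.ndarray) -> np.ndarray:
        """Pointwise p-value of the HK F test equivalent to a LOD score."""
        df2 = self.n - 2 - self.df_covar
        F = (np.power(10.0, 2.0 * np.asarray(lod, dtype=float) / self.n) - 1.0) * df2
        return stats.f.sf(F, 1, df2)


def _hk_lods(p_het: np.ndarray, Y: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Vectorized HK LOD for every position (rows) and phenotype column."""
    n = Y.shape[0]
    Yr = Y - Q @ (Q.T @ Y)
    Gr = p_het - Q @ (Q.T @ p_het)
    rss0 = np.sum(Yr * Yr, axis=0)                    # (n_pheno,)
    num = Gr.T @ Yr                                   # (P, n_pheno)
    den = np.sum(Gr * Gr, axis=0)                     # (P,)
    ok = den > 1e-12 * n
    rss1 = np.empty_like(num)
    rss1[ok] = rss0[None, :] - num[ok] ** 2 / den[ok, None]
    rss1[~ok] = rss0[None, :]
    rss1 = np.maximum(rss1, 1e-300)
    return (n / 2.0) * np.log10(rss0[None, :] / rss1)


def scan_hk(probs: GenotypeProbabilities, phenotype,
            addcovar=None, intcovar=None,
            pheno_name: str = "pheno") -> ScanResult:
    """Haley-Knott single-QTL scan.

    Individuals with missing phenotype or covariates are dropped pairwise.
    Interactive covariates add genotype x covariate terms to the full model
    (and the covariate itself to both models).
    """
    y = np.asarray(phenotype, dtype=float)
    if y.shape[0] != probs.n_individuals:
        raise ValueError("phenotype length does not match individuals")
    keep = np.isfinite(y)
    if addcovar is not None:
        keep &= np.all(np.isfinite(np.atleast_2d(np.asarray(addcovar, float).T).T),
                       axis=1)
    if intcovar is not None:
        ic = np.asarray(intcovar, dtype=float)
        if ic.ndim == 1:
            ic = ic[:, None]
        keep &= np.all(np.isfinite(ic), axis=1)
    y = y[keep]
    n = len(y)
    if n < 4:
        raise ValueError("too few informative individuals")
    if np.std(y) == 0:
        raise ValueError("phenotype is constant")
    G = probs.p_het[keep]
    ac = None if addcovar is None else np.asarray(addcovar, float)[keep]
    X0_cols = [ac] if ac is not None else []
    if intcovar is not None:
        ic = ic[keep]
        X0_cols.append(ic)
    X0 = _design(n, np.column_stack(X0_cols) if X0_cols else None)
    Q = _null_projection(X0)

    if intcovar is None:
        lods = _hk_lods(G, y[:, None], Q)[:, 0]
    else:
        # full model per position: X0 + g + g*intcovar
        Yr = y - Q @ (Q.T @ y)
        rss0 = float(Yr @ Yr)
        lods = np.empty(G.shape[1])
        for k in range(G.shape[1]):
            g = G[:, k]
            Xf = np.column_stack([X0, g, g[:, None] * ic])
            resid = y - Xf @ np.linalg.lstsq(Xf, y, rcond=None)[0]
            rss1 = max(float(resid @ resid), 1e-300)
            lods[k] = (n / 2.0) * np.log10(rss0 / rss1)

    table = probs.positions[["chrom", "pos_mb", "pos_cm", "name"]].copy()
    table["lod"] = np.maximum(lods, 0.0)
    ncov = X0.shape[1] - 1 + (0 if intcovar is None else ic.shape[1])
    return ScanResult(table=table, phenotype=pheno_name, n=n, df_covar=ncov,
                      covariates="" if addcovar is None else "additive")


@dataclass
class PermutationThreshold:
    """Genome-wide LOD threshold from a phenotype-permutation null."""

    null_max_lods: np.ndarray
    alpha: float
    value: float
    n_perm: int
    seed: int


def permute_threshold(probs: GenotypeProbabilities, phenotype,
                      addcovar=None, n_perm: int = 1000,
                      alpha: float = 0.05, seed: int = 0,
                      ) -> PermutationThreshold:
    """Permutation estimate of the genome-wide significance threshold.

    Phenotype labels are shuffled across individuals ``n_perm`` times; the
    threshold is the empirical (1 - alpha) quantile (linear, type-7
    interpolation) of the genome-wide maximum LOD.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    y = np.asarray(phenotype, dtype=float)
    keep = np.isfinite(y)
    if addcovar is not None:
        keep &= np.all(np.isfinite(np.atleast_2d(np.asarray(addcovar, float).T).T),
                       axis=1)
    y = y[keep]
    n = len(y)
    G = probs.p_het[keep]
    ac = None if addcovar is None else np.asarray(addcovar, float)[keep]
    Q = _null_projection(_design(n, ac))
    rng = np.random.default_rng(seed)
    Yp = np.empty((n, n_perm))
    for j in range(n_perm):
        Yp[:, j] = y[rng.permutation(n)]
    lods = _hk_lods(G, Yp, Q)
    max_lods = lods.max(axis=0)
    value = float(np.quantile(max_lods, 1.0 - alpha))
    return PermutationThreshold(null_max_lods=max_lods, alpha=alpha,
                                value=value, n_perm=n_perm, seed=seed)


@dataclass
class BootstrapLocalization:
    """Bootstrap peak-position profile over a chromosome region."""

    positions: pd.DataFrame      # grid rows of the region
    profile: np.ndarray          # relative frequency of peak positions
    n_boot: int
    interval: tuple              # (lo_mb, hi_mb) smallest set with coverage
    coverage: float
    seed: int


def bootstrap_localize(probs: GenotypeProbabilities, phenotype, chrom: str,
                       region_mb: tuple | None = None, n_boot: int = 1000,
                       addcovar=None, coverage: float = 0.95,
                       seed: int = 0) -> BootstrapLocalization:
    """Localize a QTL by case resampling.

    Individuals are resampled with replacement; the position of the maximum
    LOD of a single-QTL scan over the region is recorded per replicate, and
    the profile of relative peak frequencies estimates the probability of
    the QTL effect being located at each position.
    """
    if n_boot < 10:
        raise ValueError("n_boot must be >= 10")
    y = np.asarray(phenotype, dtype=float)
    keep = np.isfinite(y)
    y = y[keep]
    n = len(y)
    sl = probs.chrom_slice(chrom)
    pos = probs.positions.iloc[sl].reset_index(drop=True)
    G = probs.p_het[keep, sl]
    if region_mb is not None:
        m = (pos["pos_mb"] >= region_mb[0]) & (pos["pos_mb"] <= region_mb[1])
        pos = pos[m].reset_index(drop=True)
        G = G[:, m.to_numpy()]
    if len(pos) < 3:
        raise ValueError("region must contain at least 3 grid positions")
    ac = None if addcovar is None else np.asarray(addcovar, float)[keep]
    rng = np.random.default_rng(seed)
    counts = np.zeros(len(pos), dtype=int)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        Q = _null_projection(_design(n, None if ac is None else ac[idx]))
        lods = _hk_lods(G[idx], y[idx][:, None], Q)[:, 0]
        counts[int(np.argmax(lods))] += 1
    profile = counts / n_boot
    # smallest contiguous run of positions reaching the requested coverage
    best = (0, len(pos) - 1)
    best_len = np.inf
    for i in range(len(pos)):
        c = 0.0
        for j in range(i, len(pos)):
            c += profile[j]
            if c >= coverage - 1e-12:
                if j - i < best_len:
                    best_len = j - i
                    best = (i, j)
                break
    interval = (float(pos["pos_mb"].iloc[best[0]]),
                float(pos["pos_mb"].iloc[best[1]]))
    return BootstrapLocalization(positions=pos, profile=profile,
                                 n_boot=n_boot, interval=interval,
                                 coverage=coverage, seed=seed)
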