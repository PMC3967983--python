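"""Multiple-QTL model selection and fitting.

Model search follows the classical stepwise recipe for polygenic traits:
forward selection of additive QTLs up to a fixed model size, then backward
elimination until every remaining QTL's drop-one LOD clears a retention
threshold.  The selected model is then fitted over multiple genotype
imputations: each draw is fitted by least squares, draws are combined on
the likelihood scale (log-mean-exp), and each term is tested by removing it
from the otherwise-full model (type-III style drop-one F test).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genoprob import GenotypeProbabilities, ImputationSet
from .scan import _design, _hk_lods, _null_projection


@dataclass
class QTLTerm:
    chrom: str
    pos_mb: float

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.pos_mb:g}"


@dataclass
class QTLModel:
    """An ordered set of QTLs with optional QTL x covariate interactions."""

    qtls: list[QTLTerm] = field(default_factory=list)
    covariates: list[str] = field(default_factory=list)
    # interactions: (qtl_name, covariate_name)
    interactions: list[tuple] = field(default_factory=list)
    trace: list[str] = field(default_factory=list)

    def __post_init__(self):
        names = [q.name for q in self.qtls]
        if len(set(names)) != len(names):
            raise ValueError("duplicate QTL positions in model")

    @property
    def qtl_names(self) -> list[str]:
        return [q.name for q in self.qtls]


@dataclass
class FitResult:
    """Full-model fit with drop-one statistics.

    ``drop_table`` rows: term, df, lod, F, p, estimable.
    """

    lod: float
    varexp: float
    drop_table: pd.DataFrame
    df_resid: int
    n_imputations: int
    rss_full: float
    rss_null: float


def forward_backward_select(probs: GenotypeProbabilities, phenotype,
                            addcovar=None, max_qtl: int = 10,
                            keep_lod: float = 1.5,
                            pheno_name: str = "pheno") -> QTLModel:
    """Forward selection of additive QTLs followed by backward elimination.

    The forward step adds the genome-wide best position given the current
    model (current QTL probabilities enter as additive covariates); the
    backward step repeatedly removes the QTL with the smallest drop-one LOD
    until all remaining QTLs have drop-one LOD >= ``keep_lod``.  Ties break
    to the leftmost grid position, so the search is deterministic.
    """
    if max_qtl < 1:
        raise ValueError("max_qtl must be >= 1")
    y = np.asarray(phenotype, dtype=float)
    keep = np.isfinite(y)
    if addcovar is not None:
        ac_all = np.asarray(addcovar, float)
        if ac_all.ndim == 1:
            ac_all = ac_all[:, None]
        keep &= np.all(np.isfinite(ac_all), axis=1)
    y = y[keep]
    if np.std(y) == 0:
        raise ValueError("phenotype is constant")
    n = len(y)
    G = probs.p_het[keep]
    base = None if addcovar is None else ac_all[keep]
    pos = probs.positions
    trace = []
    model_cols: list[int] = []

    def covar_matrix(cols):
        parts = [] if base is None else [base]
        if cols:
            parts.append(G[:, cols])
        return np.column_stack(parts) if parts else None

    # forward selection
    for step in range(max_qtl):
        Q = _null_projection(_design(n, covar_matrix(model_cols)))
        lods = _hk_lods(G, y[:, None], Q)[:, 0]
        lods[model_cols] = -np.inf
        k = int(np.argmax(lods))
        model_cols.append(k)
        trace.append(f"forward: add {pos['chrom'][k]}:{pos['pos_mb'][k]:g} "
                     f"(LOD {lods[k]:.2f})")

    # backward elimination to the null model
    while model_cols:
        drop_lods = []
        for j, c in enumerate(model_cols):
            others = model_cols[:j] + model_cols[j + 1:]
            Qr = _null_projection(_design(n, covar_matrix(others)))
            drop_lods.append(float(_hk_lods(G[:, [c]], y[:, None], Qr)[0, 0]))
        worst = int(np.argmin(drop_lods))
        if drop_lods[worst] >= keep_lod:
            break
        c = model_cols.pop(worst)
        trace.append(f"backward: drop {pos['chrom'][c]}:{pos['pos_mb'][c]:g} "
                     f"(LOD {drop_lods[worst]:.2f})")

    model_cols.sort()
    qtls = [QTLTerm(str(pos["chrom"][c]), float(pos["pos_mb"][c]))
            for c in model_cols]
    return QTLModel(qtls=qtls, trace=trace)


def _term_columns(model: QTLModel, imput: ImputationSet, draw: int,
                  covar: pd.DataFrame | None) -> tuple[dict, np.ndarray]:
    """Design columns per term for one imputation draw."""
    cols = {}
    for q in model.qtls:
        c = imput.column(q.chrom, q.pos_mb)
        cols[q.name] = imput.draws[draw, :, c].astype(float)[:, None]
    for cov in model.covariates:
        cols[cov] = np.asarray(covar[cov], dtype=float)[:, None]
    for qname, cov in model.interactions:
        if qname not in cols:
            raise ValueError(f"interaction references unknown QTL {qname!r}")
        cols[f"{qname}x{cov}"] = (
            cols[qname] * np.asarray(covar[cov], dtype=float)[:, None])
    return cols, np.ones((imput.draws.shape[1], 1))


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return max(float(resid @ resid), 1e-300), rank


def _combine_rss(rss_draws: np.ndarray, n: int) -> float:
    """Effective RSS after log-mean-exp combining of draw likelihoods.

    Each draw's likelihood is proportional to RSS^(-n/2); the combined
    likelihood is their mean, re-expressed as an RSS.
    """
    logl = -(n / 2.0) * np.log(rss_draws)
    m = logl.max()
    combined = m + np.log(np.mean(np.exp(logl - m)))
    return float(np.exp(-2.0 * combined / n))


def fit_qtl(model: QTLModel, imputations: ImputationSet, phenotype,
            covar: pd.DataFrame | None = None) -> FitResult:
    """Fit a multiple-QTL model over imputation draws.

    With a single imputation on fully typed markers this reduces to plain
    OLS on the marker genotypes.  Variance explained is measured against
    the intercept-only model.
    """
    y = np.asarray(phenotype, dtype=float)
    keep = np.isfinite(y)
    yk = y[keep]
    n = len(yk)
    M = imputations.n_draws
    term_names = (model.qtl_names + list(model.covariates)
                  + [f"{q}x{c}" for q, c in model.interactions])
    rss_full = np.empty(M)
    rss_drop = {t: np.empty(M) for t in term_names}
    drop_rank_ok = {t: True for t in term_names}
    p_full = None
    for d in range(M):
        cols, intercept = _term_columns(model, imputations, d, covar)
        Xf = np.column_stack([intercept[keep]] +
                             [cols[t][keep] for t in term_names]) \
            if term_names else intercept[keep]
        rss_full[d], rank = _rss(Xf, yk)
        p_full = Xf.shape[1]
        if rank < Xf.shape[1]:
            raise ValueError("rank-deficient full model (duplicate or "
                             "collinear terms)")
        for t in term_names:
            others = [u for u in term_names if u != t]
            Xr = np.column_stack([intercept[keep]] +
                                 [cols[u][keep] for u in others]) \
                if others else intercept[keep]
            rss_d, rank_r = _rss(Xr, yk)
            rss_drop[t][d] = rss_d
            if rank_r < Xr.shape[1]:
                drop_rank_ok[t] = False
    rss_null = float(np.sum((yk - yk.mean()) ** 2))
    rss_f = _combine_rss(rss_full, n)
    df_resid = n - p_full
    lod_full = (n / 2.0) * np.log10(rss_null / rss_f)
    varexp = 100.0 * (1.0 - rss_f / rss_null)

    rows = []
    for t in term_names:
        rss_r = _combine_rss(rss_drop[t], n)
        estimable = drop_rank_ok[t] and rss_r >= rss_f * (1 - 1e-12)
        rss_r = max(rss_r, rss_f)
        lod_t = (n / 2.0) * np.log10(rss_r / rss_f)
        F = (rss_r - rss_f) / 1.0 / (rss_f / df_resid)
        p = float(stats.f.sf(F, 1, df_resid)) if estimable else np.nan
        rows.append((t, 1, lod_t, F if estimable else np.nan, p, estimable))
    drop_table = pd.DataFrame(
        rows, columns=["term", "df", "lod", "F", "p", "estimable"])
    return FitResult(lod=float(lod_full), varexp=float(varexp),
                     drop_table=drop_table, df_resid=df_resid,
                     n_imputations=M, rss_full=rss_f, rss_null=rss_null)


def drop_term_pvalue(fit: FitResult, term: str) -> float:
    """Drop-one F-test p-value of a term's contribution to the full model."""
    t = fit.drop_table
    row = t[t["term"] == term]
    if row.empty:
        raise ValueError(f"term {term!r} is not in the fitted model")
    if not bool(row["estimable"].iloc[0]):
        raise ValueError(f"term {term!r} is non-estimable in this design")
    return float(row["p"].iloc[0])
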