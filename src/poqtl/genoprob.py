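"""Conditional genotype probabilities for backcross individuals.

A backcross segregates two genotype classes at every autosomal locus
(homozygous for the recurrent strain, or heterozygous).  Along a chromosome
the true genotype follows a two-state Markov chain with Haldane transition
probabilities; observed marker genotypes are noisy emissions with a
symmetric error probability.  ``calc_genoprob`` runs the forward-backward
algorithm on a pseudomarker grid; ``sim_geno`` draws joint genotype
imputations from the same posterior by backward sampling.

Probabilities are stored flat across chromosomes: ``p_het`` has one column
per grid position, and ``positions`` describes each column (chromosome,
Mb, cM, marker name or pseudomarker label).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genmap import GeneticMap, Grid, haldane, make_grid

HOM, HET, MISSING = 0, 1, -1


def _positions_frame(grids: dict[str, Grid]) -> pd.DataFrame:
    rows = []
    for chrom, g in grids.items():
        for i in range(g.n):
            rows.append((chrom, g.pos_mb[i], g.pos_cm[i], g.names[i],
                         g.marker_index[i]))
    return pd.DataFrame(
        rows, columns=["chrom", "pos_mb", "pos_cm", "name", "marker_index"])


@dataclass
class GenotypeProbabilities:
    """P(heterozygous) per individual and grid position."""

    gmap: GeneticMap
    positions: pd.DataFrame      # chrom, pos_mb, pos_cm, name, marker_index
    p_het: np.ndarray            # individuals x positions
    step_mb: float
    error_prob: float

    @property
    def n_individuals(self) -> int:
        return self.p_het.shape[0]

    @property
    def n_positions(self) -> int:
        return self.p_het.shape[1]

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero((self.positions["chrom"] == str(chrom)).to_numpy())
        if len(idx) == 0:
            raise KeyError(f"no grid positions on chromosome {chrom}")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def column(self, chrom: str, pos_mb: float) -> int:
        """Index of the grid position nearest to (chrom, pos_mb)."""
        sl = self.chrom_slice(chrom)
        mb = self.positions["pos_mb"].to_numpy()[sl]
        return sl.start + int(np.argmin(np.abs(mb - pos_mb)))

    def subset(self, individuals: np.ndarray) -> "GenotypeProbabilities":
        return GenotypeProbabilities(
            gmap=self.gmap, positions=self.positions,
            p_het=self.p_het[np.asarray(individuals)],
            step_mb=self.step_mb, error_prob=self.error_prob)


@dataclass
class ImputationSet:
    """Hard genotype draws from the HMM posterior.

    ``draws[d, i, k]`` is the imputed genotype class (0 hom, 1 het) of
    individual ``i`` at grid position ``k`` in draw ``d``; each draw is a
    valid Markov path consistent with the observed markers.
    """

    gmap: GeneticMap
    positions: pd.DataFrame
    draws: np.ndarray            # n_draws x individuals x positions, int8
    step_mb: float
    error_prob: float
    seed: int

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def column(self, chrom: str, pos_mb: float) -> int:
        sl_idx = np.flatnonzero((self.positions["chrom"] == str(chrom)).to_numpy())
        mb = self.positions["pos_mb"].to_numpy()[sl_idx]
        return int(sl_idx[np.argmin(np.abs(mb - pos_mb))])


def _check_inputs(genotypes: np.ndarray, gmap: GeneticMap, step_mb: float,
                  error_prob: float) -> np.ndarray:
    g = np.asarray(genotypes)
    if g.ndim != 2:
        raise ValueError("genotype matrix must be individuals x markers")
    if g.shape[1] != gmap.n_markers:
        raise ValueError(
            f"genotype matrix has {g.shape[1]} markers, map has {gmap.n_markers}")
    bad = ~np.isin(g, (HOM, HET, MISSING))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid genotype code {g[i, j]!r} for individual {i}, "
            f"marker {gmap.marker_names[j]!r}")
    if step_mb < 0:
        raise ValueError("step must be >= 0")
    if not 0 <= error_prob < 0.5:
        raise ValueError("error_prob must be in [0, 0.5)")
    return g.astype(np.int8)


def _emissions(g: np.ndarray, grid: Grid, error_prob: float) -> np.ndarray:
    """Emission likelihood (n x grid positions x 2 states)."""
    n = g.shape[0]
    E = np.ones((n, grid.n, 2))
    e = error_prob
    for k in range(grid.n):
        mcol = grid.marker_index[k]
        if mcol < 0:
            continue
        obs = g[:, mcol]
        hom_mask = obs == HOM
        het_mask = obs == HET
        E[hom_mask, k, 0] = 1 - e
        E[hom_mask, k, 1] = e
        E[het_mask, k, 0] = e
        E[het_mask, k, 1] = 1 - e
    return E


def _forward(E: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Scaled forward variables; returns f (n x pos x 2), normalized per
    position.  The Markov prior is uniform (0.5, 0.5)."""
    n, npos, _ = E.shape
    f = np.empty_like(E)
    f[:, 0, :] = 0.5 * E[:, 0, :]
    f[:, 0, :] /= f[:, 0, :].sum(axis=1, keepdims=True)
    for k in range(1, npos):
        rk = r[k - 1]
        stay, move = 1.0 - rk, rk
        prev = f[:, k - 1, :]
        f[:, k, 0] = (prev[:, 0] * stay + prev[:, 1] * move) * E[:, k, 0]
        f[:, k, 1] = (prev[:, 0] * move + prev[:, 1] * stay) * E[:, k, 1]
        f[:, k, :] /= f[:, k, :].sum(axis=1, keepdims=True)
    return f


def _backward(E: np.ndarray, r: np.ndarray) -> np.ndarray:
    n, npos, _ = E.shape
    b = np.empty_like(E)
    b[:, -1, :] = 1.0
    for k in range(npos - 2, -1, -1):
        rk = r[k]
        stay, move = 1.0 - rk, rk
        nxt = b[:, k + 1, :] * E[:, k + 1, :]
        b[:, k, 0] = nxt[:, 0] * stay + nxt[:, 1] * move
        b[:, k, 1] = nxt[:, 0] * move + nxt[:, 1] * stay
        b[:, k, :] /= b[:, k, :].sum(axis=1, keepdims=True)
    return b


def calc_genoprob(genotypes: np.ndarray, gmap: GeneticMap,
                  step_mb: float = 1.0, error_prob: float = 1e-4,
                  ) -> GenotypeProbabilities:
    """Posterior P(het) at every marker and pseudomarker.

    Per-position rescaling keeps the recursion numerically stable; the
    posterior marginals are invariant to the scaling.
    """
    g = _check_inputs(genotypes, gmap, step_mb, error_prob)
    grids = make_grid(gmap, step_mb)
    n = g.shape[0]
    cols = []
    for chrom in gmap.chromosomes:
        grid = grids[chrom]
        E = _emissions(g, grid, error_prob)
        r = haldane(np.diff(grid.pos_cm))
        f = _forward(E, r)
        b = _backward(E, r)
        post = f * b
        cols.append(post[:, :, 1] / post.sum(axis=2))
    return GenotypeProbabilities(
        gmap=gmap, positions=_positions_frame(grids),
        p_het=np.concatenate(cols, axis=1) if cols else np.empty((n, 0)),
        step_mb=step_mb, error_prob=error_prob)


def sim_geno(genotypes: np.ndarray, gmap: GeneticMap, n_draws: int = 128,
             step_mb: float = 1.0, error_prob: float = 1e-4,
             seed: int = 0) -> ImputationSet:
    """Joint genotype imputations by backward sampling from the HMM.

    Over many draws the empirical per-position het frequency converges to
    the ``calc_genoprob`` marginals.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    g = _check_inputs(genotypes, gmap, step_mb, error_prob)
    grids = make_grid(gmap, step_mb)
    rng = np.random.default_rng(seed)
    n = g.shape[0]
    chrom_draws = []
    for chrom in gmap.chromosomes:
        grid = grids[chrom]
        E = _emissions(g, grid, error_prob)
        r = haldane(np.diff(grid.pos_cm))
        f = _forward(E, r)
        npos = grid.n
        states = np.empty((n_draws, n, npos), dtype=np.int8)
        p1 = f[:, -1, 1]                       # filtered marginal at the end
        states[:, :, -1] = rng.random((n_draws, n)) < p1[None, :]
        for k in range(npos - 2, -1, -1):
            rk = r[k]
            nxt = states[:, :, k + 1]
            # P(s_k | s_{k+1}, obs_{1..k}) ∝ f_k(s) * T(s -> s_{k+1})
            w1 = f[:, k, 1][None, :] * np.where(nxt == 1, 1.0 - rk, rk)
            w0 = f[:, k, 0][None, :] * np.where(nxt == 0, 1.0 - rk, rk)
            states[:, :, k] = rng.random((n_draws, n)) < w1 / (w0 + w1)
        chrom_draws.append(states)
    return ImputationSet(
        gmap=gmap, positions=_positions_frame(grids),
        draws=np.concatenate(chrom_draws, axis=2),
        step_mb=step_mb, error_prob=error_prob, seed=seed)
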