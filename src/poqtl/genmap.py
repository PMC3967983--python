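"""Genetic maps for experimental crosses.

A :class:`GeneticMap` holds ordered marker positions per chromosome in both
physical (Mb) and genetic (cM) coordinates.  The two coordinate systems are
related by a configurable linear rate (default 0.55 cM/Mb), which is adequate
for microsatellite framework maps at 20-25 cM spacing.  The map is the
backbone for recombination simulation, the genotype-probability HMM and the
genome scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: default linear conversion between physical and genetic distance
DEFAULT_CM_PER_MB = 0.55


def haldane(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction for a genetic distance under the Haldane map.

    Assumes crossovers arrive as a Poisson process (no interference):
    ``r = (1 - exp(-2 d / 100)) / 2`` for ``d`` in cM.
    """
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("genetic distances must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if np.isscalar(d_cm) else r


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker positions on a set of chromosomes.

    Parameters
    ----------
    table
        DataFrame with columns ``marker``, ``chrom``, ``pos_cm``, ``pos_mb``.
        Positions must be strictly increasing within each chromosome.
    cm_per_mb
        Linear rate relating the two coordinate systems.
    """

    table: pd.DataFrame
    cm_per_mb: float = DEFAULT_CM_PER_MB
    _by_chrom: dict = field(init=False, repr=False, default=None)

    def __post_init__(self):
        t = self.table
        required = {"marker", "chrom", "pos_cm", "pos_mb"}
        if not required.issubset(t.columns):
            raise ValueError(f"map table needs columns {sorted(required)}")
        if len(t) == 0:
            raise ValueError("empty genetic map")
        if t["marker"].duplicated().any():
            dup = t.loc[t["marker"].duplicated(), "marker"].iloc[0]
            raise ValueError(f"duplicate marker name: {dup}")
        by = {}
        for chrom, sub in t.groupby("chrom", sort=False):
            pos = sub["pos_cm"].to_numpy(float)
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
            by[str(chrom)] = sub.reset_index(drop=True)
        object.__setattr__(self, "_by_chrom", by)

    # -- accessors ---------------------------------------------------------

    @property
    def chromosomes(self) -> list[str]:
        return list(self._by_chrom)

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def marker_names(self) -> list[str]:
        return self.table["marker"].tolist()

    def chrom(self, chrom: str) -> pd.DataFrame:
        return self._by_chrom[str(chrom)]

    def positions_cm(self, chrom: str) -> np.ndarray:
        return self.chrom(chrom)["pos_cm"].to_numpy(float)

    def positions_mb(self, chrom: str) -> np.ndarray:
        return self.chrom(chrom)["pos_mb"].to_numpy(float)

    def mb_to_cm(self, mb: float) -> float:
        return float(mb) * self.cm_per_mb

    def contains(self, chrom: str, pos_mb: float) -> bool:
        if str(chrom) not in self._by_chrom:
            return False
        mb = self.positions_mb(chrom)
        return mb[0] - 1e-9 <= pos_mb <= mb[-1] + 1e-9


def make_map(lengths_cm: dict[str, float], n_markers: dict[str, int],
             cm_per_mb: float = DEFAULT_CM_PER_MB,
             prefix: str = "M") -> GeneticMap:
    """Build an evenly spaced framework map.

    ``n_markers`` markers are placed per chromosome from 0 cM to the
    chromosome length inclusive.
    """
    rows = []
    for chrom, length in lengths_cm.items():
        k = n_markers[chrom]
        if k < 2:
            raise ValueError("need at least two markers per chromosome")
        cm = np.linspace(0.0, length, k)
        for i, p in enumerate(cm):
            rows.append((f"{prefix}{chrom}_{i + 1}", str(chrom), p, p / cm_per_mb))
    return GeneticMap(
        pd.DataFrame(rows, columns=["marker", "chrom", "pos_cm", "pos_mb"]),
        cm_per_mb=cm_per_mb,
    )


# Marker counts per autosome for the default rat-style framework map: 140
# microsatellites over 20 autosomes at ~20 cM spacing, denser on the longer
# chromosomes.
_DEFAULT_COUNTS = [10, 9, 9, 8, 8, 8, 7, 7, 7, 7, 7, 7, 6, 6, 6, 6, 6, 6, 5, 5]


def default_rat_map(spacing_cm: float = 20.0,
                    cm_per_mb: float = DEFAULT_CM_PER_MB) -> GeneticMap:
    """A stylized 20-autosome, 140-marker framework map.

    Marker spacing defaults to 20 cM, the denser of the two spacings used for
    microsatellite genome coverage in rat linkage studies.
    """
    lengths = {str(i + 1): (c - 1) * spacing_cm
               for i, c in enumerate(_DEFAULT_COUNTS)}
    counts = {str(i + 1): c for i, c in enumerate(_DEFAULT_COUNTS)}
    return make_map(lengths, counts, cm_per_mb=cm_per_mb)


@dataclass(frozen=True)
class Grid:
    """Evaluation grid for one chromosome: markers plus pseudomarkers.

    Attributes
    ----------
    chrom : chromosome identifier
    pos_mb, pos_cm : grid coordinates, strictly increasing
    marker_index : for each grid point, the column index into the marker
        genotype matrix, or -1 for a pseudomarker.
    names : marker name, or ``c{chrom}.loc{Mb}`` for pseudomarkers
    """

    chrom: str
    pos_mb: np.ndarray
    pos_cm: np.ndarray
    marker_index: np.ndarray
    names: list[str]

    @property
    def n(self) -> int:
        return len(self.pos_mb)


def make_grid(gmap: GeneticMap, step_mb: float = 1.0) -> dict[str, Grid]:
    """Insert pseudomarkers between markers at a fixed physical step.

    ``step_mb = 0`` yields a markers-only grid.  Pseudomarkers are placed at
    multiples of the step strictly inside each marker interval, so every
    marker is retained and no positions are duplicated.
    """
    if step_mb < 0:
        raise ValueError("step must be >= 0")
    marker_offset = 0
    grids: dict[str, Grid] = {}
    for chrom in gmap.chromosomes:
        sub = gmap.chrom(chrom)
        mb = sub["pos_mb"].to_numpy(float)
        names = sub["marker"].tolist()
        pos, midx, gnames = [], [], []
        for i in range(len(mb)):
            pos.append(mb[i])
            midx.append(marker_offset + i)
            gnames.append(names[i])
            if step_mb > 0 and i + 1 < len(mb):
                # interior pseudomarkers at multiples of the step
                start = np.floor(mb[i] / step_mb) * step_mb + step_mb
                p = start
                while p < mb[i + 1] - 1e-9:
                    if p > mb[i] + 1e-9:
                        pos.append(p)
                        midx.append(-1)
                        gnames.append(f"c{chrom}.loc{p:g}")
                    p += step_mb
        pos = np.asarray(pos)
        # genetic coordinates of pseudomarkers by interpolation between
        # flanking markers (exact when the map is linear in Mb)
        cm = np.interp(pos, mb, sub["pos_cm"].to_numpy(float))
        grids[chrom] = Grid(
            chrom=chrom,
            pos_mb=pos,
            pos_cm=cm,
            marker_index=np.asarray(midx, dtype=int),
            names=gnames,
        )
        marker_offset += len(mb)
    return grids
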