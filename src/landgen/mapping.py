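"""Grid-based diversity mapping with circular neighborhoods.

Each genotyped tree with coordinates is replicated into every 30 arc-second
grid cell whose center falls inside a circle of 10 arc-minutes diameter
around the tree. Because cells then hold unequal numbers of trees, per-cell
statistics are bias-corrected by averaging over bootstrapped subsamples of
the minimum cell size (3 trees by default, 1,000 subsamples drawn without
replacement — i.e. rarefaction). Mapped statistics are allelic richness,
Shannon index, expected/observed heterozygosity, the inbreeding
coefficient, and locally-common-allele (LCA) richness per locus.

An allele is *locally common* when it occurs in fewer than 25% of the
sampled populations yet exceeds 5% frequency in at least one population
where it occurs; LCA richness flags putatively long-isolated stands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .popgen import _fis_of_calls, _locus_frequencies, _per_locus_stats, allele_frequencies
from .raster import CELL_30_ARCSEC, Grid, Raster
from .types import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: 10 arc minutes in decimal degrees (neighborhood circle diameter)
DIAMETER_10_ARCMIN = 10.0 / 60.0


class MappingError(ValueError):
    pass


# ----------------------------------------------------------------------
# Neighborhood grid
# ----------------------------------------------------------------------

@dataclass
class NeighborhoodGrid:
    """Per-cell tree membership from circular-neighborhood replication."""

    grid: Grid
    members: dict[tuple[int, int], np.ndarray]  # cell -> tree indices
    diameter: float
    tree_indices: np.ndarray  # trees (with coordinates) that contributed

    def counts(self) -> Raster:
        vals = np.zeros(self.grid.shape)
        for (r, c), idx in self.members.items():
            vals[r, c] = len(idx)
        return Raster(grid=self.grid, values=vals, nodata=-9999.0)


def build_neighborhood_grid(
    G: GenotypeMatrix,
    cell_size: float = CELL_30_ARCSEC,
    diameter: float = DIAMETER_10_ARCMIN,
) -> NeighborhoodGrid:
    """Replicate each tree into all cells with centers inside its circle.

    Membership is a center-in-circle test in geographic degree space
    (radius = ``diameter / 2``); the grid is snapped to the global lattice
    and extended so every circle fits.
    """
    if G.coordinates is None:
        raise MappingError("genotype matrix has no coordinates")
    has_xy = ~np.isnan(G.coordinates).any(axis=1)
    if not has_xy.all():
        logger.warning("%d trees without coordinates excluded from mapping",
                       int((~has_xy).sum()))
    trees = np.where(has_xy)[0]
    if trees.size == 0:
        raise MappingError("no trees with coordinates")
    xy = G.coordinates[trees]
    r = diameter / 2.0
    grid = Grid.snapped(
        west=xy[:, 0].min() - r - cell_size,
        south=xy[:, 1].min() - r - cell_size,
        east=xy[:, 0].max() + r + cell_size,
        north=xy[:, 1].max() + r + cell_size,
        cell_size=cell_size,
    )
    members: dict[tuple[int, int], list[int]] = {}
    n_span = int(np.ceil(r / cell_size)) + 1
    for t, (lon, lat) in zip(trees, xy):
        row0, col0 = grid.index_of(lon, lat)
        rows = np.arange(max(row0 - n_span, 0), min(row0 + n_span + 1, grid.nrows))
        cols = np.arange(max(col0 - n_span, 0), min(col0 + n_span + 1, grid.ncols))
        cc, rr = np.meshgrid(cols, rows)
        clon, clat = grid.cell_center(rr, cc)
        inside = (clon - lon) ** 2 + (clat - lat) ** 2 <= r ** 2
        for row, col in zip(rr[inside], cc[inside]):
            members.setdefault((int(row), int(col)), []).append(int(t))
    return NeighborhoodGrid(
        grid=grid,
        members={k: np.array(sorted(v), dtype=int) for k, v in members.items()},
        diameter=diameter,
        tree_indices=trees,
    )


# ----------------------------------------------------------------------
# Bootstrap-corrected statistics
# ----------------------------------------------------------------------

def bootstrap_corrected_stat(
    trees: np.ndarray,
    stat: Callable[[np.ndarray], float],
    n_boot: int = 1000,
    subsample: int = 3,
    seed: int | None = None,
    replace: bool = False,
) -> tuple[float, float] | None:
    """Mean and sd of ``stat`` over subsamples of fixed size.

    ``stat`` receives an array of tree indices. Subsamples are drawn
    *without* replacement by default (rarefaction); when the set is exactly
    the subsample size the statistic is returned directly with sd 0, so the
    corrected value equals the uncorrected one at minimum sample size.
    Returns ``None`` (no-data) when fewer trees than ``subsample``.
    """
    trees = np.asarray(trees)
    if trees.size < subsample:
        return None
    if trees.size == subsample and not replace:
        return float(stat(trees)), 0.0
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.choice(trees, size=subsample, replace=replace)
        vals[b] = stat(pick)
    return float(vals.mean()), float(vals.std(ddof=0))


# ----------------------------------------------------------------------
# Locally common alleles
# ----------------------------------------------------------------------

@dataclass
class LcaClassification:
    """Per-locus sets of locally common allele codes."""

    lca: dict[str, set[int]]       # locus name -> allele codes
    occupancy_fraction: float
    frequency_threshold: float
    n_populations: int

    def is_lca(self, locus: str, allele: int) -> bool:
        return allele in self.lca.get(locus, set())


def classify_lca(
    G: GenotypeMatrix,
    occupancy_fraction: float = 0.25,
    frequency_threshold: float = 0.05,
) -> LcaClassification:
    """Classify alleles as locally common from the full dataset.

    An allele qualifies iff it occurs in strictly fewer than
    ``occupancy_fraction`` of the sampled populations AND reaches a
    frequency strictly above ``frequency_threshold`` in at least one
    population where it occurs. The classification is computed once on the
    whole dataset and then reused for every cell.
    """
    freqs = allele_frequencies(G, by="population")
    pops = G.populations
    n_pops = len(pops)
    lca: dict[str, set[int]] = {name: set() for name in G.locus_names}
    for l, locus in enumerate(G.locus_names):
        presence: dict[int, int] = {}
        max_freq: dict[int, float] = {}
        for p in pops:
            lf = freqs[p][l]
            for a, f in zip(lf.alleles, lf.frequencies):
                a = int(a)
                presence[a] = presence.get(a, 0) + 1
                max_freq[a] = max(max_freq.get(a, 0.0), float(f))
        for a, n_present in presence.items():
            if (n_present < occupancy_fraction * n_pops
                    and max_freq[a] > frequency_threshold):
                lca[locus].add(a)
    return LcaClassification(
        lca=lca,
        occupancy_fraction=occupancy_fraction,
        frequency_threshold=frequency_threshold,
        n_populations=n_pops,
    )


def lca_per_locus(
    G: GenotypeMatrix, trees: np.ndarray, classification: LcaClassification
) -> float:
    """Number of classified-LCA alleles present in the tree set, per locus."""
    trees = np.asarray(trees)
    if trees.size == 0:
        return np.nan
    count = 0
    for l, locus in enumerate(G.locus_names):
        lca_set = classification.lca.get(locus, set())
        if not lca_set:
            continue
        copies = G.calls[trees, l, :].ravel()
        present = set(int(a) for a in copies[copies != MISSING])
        count += len(present & lca_set)
    return count / G.n_loci


# ----------------------------------------------------------------------
# Statistic registry and raster mapping
# ----------------------------------------------------------------------

def _fast_multilocus(calls: np.ndarray) -> dict[str, float]:
    """Multilocus A/I/He/Ho/Fis means without DataFrame overhead.

    Matches :func:`landgen.popgen._per_locus_stats` with the biased He
    estimator; loci with no scored individuals are dropped from the means.
    """
    A: list[float] = []
    I: list[float] = []
    He: list[float] = []
    Ho: list[float] = []
    for l in range(calls.shape[1]):
        col = calls[:, l, :]
        scored = col[:, 0] != MISSING
        if not scored.any():
            continue
        copies = col[scored].ravel()
        _, counts = np.unique(copies, return_counts=True)
        p = counts / copies.size
        A.append(float(len(counts)))
        I.append(float(-np.sum(p * np.log(p))))
        He.append(1.0 - float(np.sum(p ** 2)))
        Ho.append(float(np.mean(col[scored, 0] != col[scored, 1])))
    if not A:
        return dict(A=np.nan, I=np.nan, He=np.nan, Ho=np.nan, Fis=np.nan)
    he, ho = float(np.mean(He)), float(np.mean(Ho))
    return dict(A=float(np.mean(A)), I=float(np.mean(I)), He=he, Ho=ho,
                Fis=(1.0 - ho / he) if he > 0 else np.nan)


def _make_stat_fn(
    G: GenotypeMatrix, stat_name: str,
    classification: LcaClassification | None,
) -> Callable[[np.ndarray], float]:
    """Statistic over a set of tree indices, computed from that subsample
    alone (per-cell Fis uses the subsample's own Ho/He)."""
    if stat_name in {"A", "I", "He", "Ho", "Fis"}:
        def fn(trees: np.ndarray) -> float:
            return _fast_multilocus(G.calls[np.asarray(trees)])[stat_name]
        return fn
    if stat_name == "LCA":
        if classification is None:
            raise MappingError("LCA mapping requires a classification")
        return lambda trees: lca_per_locus(G, trees, classification)
    raise MappingError(f"unknown statistic {stat_name!r}; "
                       "expected one of A, I, He, Ho, Fis, LCA")


@dataclass
class DiversityRaster:
    """Bootstrap-corrected per-cell statistic raster plus provenance."""

    raster: Raster
    sd: Raster
    counts: Raster
    stat_name: str
    n_boot: int
    subsample: int
    seed: int | None
    table: pd.DataFrame = field(repr=False, default=None)


def map_statistic(
    G: GenotypeMatrix,
    stat_name: str,
    cell_size: float = CELL_30_ARCSEC,
    diameter: float = DIAMETER_10_ARCMIN,
    n_boot: int = 1000,
    subsample: int = 3,
    seed: int | None = 0,
    neighborhood: NeighborhoodGrid | None = None,
    classification: LcaClassification | None = None,
) -> DiversityRaster:
    """Bootstrap-corrected raster of one statistic over the neighborhood grid.

    Cells holding fewer trees than ``subsample`` are no-data. A precomputed
    ``neighborhood`` (and LCA ``classification``) can be passed to amortize
    work across statistics.
    """
    ng = neighborhood or build_neighborhood_grid(G, cell_size, diameter)
    if stat_name == "LCA" and classification is None:
        classification = classify_lca(G)
    stat = _make_stat_fn(G, stat_name, classification)
    vals = np.full(ng.grid.shape, np.nan)
    sds = np.full(ng.grid.shape, np.nan)
    rows = []
    rng = np.random.default_rng(seed)

    def content_key(t: int) -> tuple:
        xy = (tuple(G.coordinates[t]) if G.coordinates is not None else ())
        return (*xy, G.calls[t].tobytes(), G.individual_ids[t])

    # cells sharing the exact same tree membership get one computation;
    # trees are ordered by content so raster values do not depend on the
    # input order of individuals
    cache: dict[tuple[int, ...], tuple[float, float] | None] = {}
    for (r, c), trees in sorted(ng.members.items()):
        trees = np.array(sorted(trees, key=content_key), dtype=int)
        key = tuple(trees)
        if key not in cache:
            cache[key] = bootstrap_corrected_stat(
                trees, stat, n_boot=n_boot, subsample=subsample,
                seed=int(rng.integers(2 ** 31)),
            )
        res = cache[key]
        if res is None:
            continue
        vals[r, c], sds[r, c] = res
        lon, lat = ng.grid.cell_center(r, c)
        rows.append(dict(row=r, col=c, lon=float(lon), lat=float(lat),
                         n_trees=len(trees), value=vals[r, c], sd=sds[r, c]))
    return DiversityRaster(
        raster=Raster(ng.grid, vals),
        sd=Raster(ng.grid, sds),
        counts=ng.counts(),
        stat_name=stat_name,
        n_boot=n_boot,
        subsample=subsample,
        seed=seed,
        table=pd.DataFrame(rows),
    )
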