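"""Synthetic genotype and landscape generators with known truth.

Genotypes follow the Balding-Nichols construction: per locus an ancestral
allele-frequency vector is drawn from a symmetric Dirichlet, and each of
``K_true`` clusters gets frequencies from ``Dirichlet(p (1 - F) / F)``, so
cluster frequencies scatter around the ancestral ones with variance
``F p (1 - p)`` — ``F`` plays the role of the expected F_ST. Individuals
carry ancestry vectors Q (pure by site, or Dirichlet-admixed), each allele
copy picks a cluster by Q and an allele by that cluster's frequencies, and
within-individual inbreeding is injected at the genotype draw: the second
allele copies the first with the excess-homozygosity probability implied by
``P(hom a) = p_a^2 + Fis p_a (1 - p_a)`` (negative Fis yields heterozygote
excess; infeasible values are clipped cellwise).

The default configuration mirrors a 12-site, 100-tree SSR survey with 12
loci carrying 13-28 alleles each, sites of 3-14 trees scattered over an
~8 x 8 degree extent (so 10-arc-minute neighborhoods of distinct sites
never merge).

Landscapes are stacks of spatially autocorrelated Gaussian layers with a
logistic true-suitability surface and presence points sampled
proportionally to it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .raster import Grid
from .sdm import EnvStack
from .types import GenotypeMatrix, OccurrenceSet

logger = logging.getLogger(__name__)

#: site sizes echoing a 12-site, 100-tree survey design (3-14 trees/site)
DEFAULT_SITE_SIZES = (3, 7, 14, 10, 7, 12, 12, 10, 3, 5, 6, 11)


def _default_site_coordinates(n_sites: int, rng: np.random.Generator) -> np.ndarray:
    """Scatter sites over ~8x8 degrees with >= 0.5 degree separation."""
    coords = []
    while len(coords) < n_sites:
        cand = np.array([-76.0, 2.0]) + rng.uniform(0, 8, size=2)
        if all(np.hypot(*(cand - c)) > 0.5 for c in coords):
            coords.append(cand)
    return np.array(coords)


@dataclass
class GenotypeSimConfig:
    """Parameters of the Balding-Nichols genotype generator."""

    K_true: int = 3
    F: float = 0.15
    Fis: float = 0.0
    n_pops: int = 12
    site_sizes: tuple[int, ...] | None = DEFAULT_SITE_SIZES
    n_per_pop: int = 8                       # used when site_sizes is None
    n_loci: int = 12
    alleles_min: int = 13
    alleles_max: int = 28
    admixture_alpha: float | None = None     # None = pure site ancestry
    site_coordinates: np.ndarray | None = None
    coord_jitter: float = 0.01               # degrees, within-site scatter
    missing_rate: float = 0.0
    seed: int | None = 0
    clusters_equal_pops: bool = False        # one BN draw per population

    def __post_init__(self) -> None:
        if not 0 < self.F < 1:
            raise ValueError("F must be in (0, 1)")
        if not -1 < self.Fis < 1:
            raise ValueError("Fis must be in (-1, 1)")
        if self.alleles_min < 2:
            raise ValueError("need at least 2 alleles per locus")


@dataclass
class GenotypeTruth:
    """Ground truth stored by the generator for recovery tests."""

    Q: np.ndarray                   # (n, K) ancestry
    P: list[np.ndarray]             # per locus (K, A_l) cluster frequencies
    ancestral: list[np.ndarray]     # per locus ancestral frequencies
    F: float
    Fis: float
    cluster_of_pop: np.ndarray
    config: GenotypeSimConfig


def _draw_pair(rng, p_i: np.ndarray, fis: float) -> tuple[int, int]:
    """One diploid genotype from mixture frequencies with inbreeding.

    Conditional construction: a1 ~ p; P(a2 = a1 | a1) = p_a1 + fis (1 - p_a1)
    (clipped into [0, 1]); otherwise a2 is drawn from p restricted to other
    alleles. This realizes P(hom a) = p_a^2 + fis p_a (1 - p_a) wherever
    that is a valid probability.
    """
    a1 = rng.choice(len(p_i), p=p_i)
    p1 = p_i[a1]
    p_same = np.clip(p1 + fis * (1.0 - p1), 0.0, 1.0)
    if rng.random() < p_same:
        return a1, a1
    rest = p_i.copy()
    rest[a1] = 0.0
    tot = rest.sum()
    if tot <= 0:
        return a1, a1
    a2 = rng.choice(len(p_i), p=rest / tot)
    return a1, a2


def simulate_genotypes(cfg: GenotypeSimConfig) -> tuple[GenotypeMatrix, GenotypeTruth]:
    """Generate a GenotypeMatrix plus the truth record.

    With ``clusters_equal_pops`` each population is its own Balding-Nichols
    draw (K_true is ignored), the design used for differentiation-recovery
    tests; otherwise populations are assigned round-robin to ``K_true``
    ancestral clusters.
    """
    rng = np.random.default_rng(cfg.seed)
    sizes = (list(cfg.site_sizes) if cfg.site_sizes is not None
             else [cfg.n_per_pop] * cfg.n_pops)
    if len(sizes) != cfg.n_pops:
        raise ValueError("site_sizes length must equal n_pops")
    n = int(sum(sizes))
    K = cfg.n_pops if cfg.clusters_equal_pops else cfg.K_true
    cluster_of_pop = (np.arange(cfg.n_pops) if cfg.clusters_equal_pops
                      else np.arange(cfg.n_pops) % K)

    n_alleles = rng.integers(cfg.alleles_min, cfg.alleles_max + 1,
                             size=cfg.n_loci)
    ancestral: list[np.ndarray] = []
    P: list[np.ndarray] = []
    for l in range(cfg.n_loci):
        p = rng.dirichlet(np.ones(n_alleles[l]))
        # Balding-Nichols: cluster freqs ~ Dirichlet(p (1-F)/F)
        conc = np.maximum(p * (1.0 - cfg.F) / cfg.F, 1e-6)
        P.append(np.vstack([rng.dirichlet(conc) for _ in range(K)]))
        ancestral.append(p)

    pop_labels: list[str] = []
    ids: list[str] = []
    Q = np.zeros((n, K))
    coords = np.zeros((n, 2))
    site_xy = (cfg.site_coordinates if cfg.site_coordinates is not None
               else _default_site_coordinates(cfg.n_pops, rng))
    i = 0
    for s, size in enumerate(sizes):
        label = f"S{s + 1:02d}"
        for _ in range(size):
            ids.append(f"{label}_{_ + 1}")
            pop_labels.append(label)
            if cfg.admixture_alpha is None:
                Q[i, cluster_of_pop[s]] = 1.0
            else:
                Q[i] = rng.dirichlet(np.full(K, cfg.admixture_alpha))
            coords[i] = site_xy[s] + rng.normal(0, cfg.coord_jitter, 2)
            i += 1

    calls = np.zeros((n, cfg.n_loci, 2), dtype=np.int64)
    for l in range(cfg.n_loci):
        # allele codes 1..A_l (0 reserved for missing)
        for ind in range(n):
            p_i = Q[ind] @ P[l]
            a1, a2 = _draw_pair(rng, p_i, cfg.Fis)
            calls[ind, l] = (a1 + 1, a2 + 1)
    if cfg.missing_rate > 0:
        mask = rng.random((n, cfg.n_loci)) < cfg.missing_rate
        calls[mask] = 0

    G = GenotypeMatrix(
        individual_ids=ids, population_labels=pop_labels, calls=calls,
        locus_names=[f"L{l + 1:02d}" for l in range(cfg.n_loci)],
        coordinates=coords,
    )
    truth = GenotypeTruth(Q=Q, P=P, ancestral=ancestral, F=cfg.F,
                          Fis=cfg.Fis, cluster_of_pop=cluster_of_pop,
                          config=cfg)
    return G, truth


# ----------------------------------------------------------------------
# Landscapes
# ----------------------------------------------------------------------

@dataclass
class LandscapeSimConfig:
    """Parameters of the synthetic environment/presence generator."""

    nrows: int = 100
    ncols: int = 100
    n_layers: int = 4
    autocorr_sigma: float = 8.0           # cells; Gaussian-filter length
    coefficients: np.ndarray | None = None
    intercept: float = -4.0
    n_presences: int = 151
    west: float = -78.0
    north: float = 8.0
    cell_size: float = 1.0 / 120.0
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.nrows < 10 or self.ncols < 10:
            raise ValueError("grid too small")


@dataclass
class LandscapeTruth:
    coefficients: np.ndarray
    intercept: float
    suitability: np.ndarray
    config: LandscapeSimConfig


def simulate_landscape(
    cfg: LandscapeSimConfig,
) -> tuple[EnvStack, OccurrenceSet, LandscapeTruth]:
    """Correlated environmental layers, logistic truth, presence sample.

    Layers are unit-variance Gaussian fields smoothed to the configured
    autocorrelation length; true suitability is
    ``sigmoid(intercept + sum(coef * layer))`` and ``n_presences`` distinct
    cells are drawn with probability proportional to suitability.
    """
    rng = np.random.default_rng(cfg.seed)
    grid = Grid(west=cfg.west, north=cfg.north, cell_size=cfg.cell_size,
                nrows=cfg.nrows, ncols=cfg.ncols)
    layers: dict[str, np.ndarray] = {}
    fields = []
    for j in range(cfg.n_layers):
        z = rng.normal(size=(cfg.nrows, cfg.ncols))
        if cfg.autocorr_sigma > 0:
            z = gaussian_filter(z, cfg.autocorr_sigma, mode="reflect")
        z = (z - z.mean()) / z.std()
        layers[f"env{j + 1}"] = z
        fields.append(z)

    coef = (np.asarray(cfg.coefficients, float)
            if cfg.coefficients is not None
            else np.r_[5.0, -4.0, np.zeros(max(cfg.n_layers - 2, 0))])
    if len(coef) != cfg.n_layers:
        raise ValueError("coefficients length must equal n_layers")
    if not np.any(coef):
        logger.warning("all-zero coefficients: uniform suitability surface")
    eta = cfg.intercept + sum(c * f for c, f in zip(coef, fields))
    suit = 1.0 / (1.0 + np.exp(-eta))

    p = suit.ravel() / suit.sum()
    n_cells = p.size
    n_pres = min(cfg.n_presences, n_cells)
    pick = rng.choice(n_cells, size=n_pres, replace=False, p=p)
    rows, cols = np.unravel_index(pick, suit.shape)
    lon, lat = grid.cell_center(rows, cols)
    occ = OccurrenceSet(points=np.column_stack([lon, lat]),
                        sources=["synthetic"] * n_pres)
    stack = EnvStack(grid=grid, layers=layers)
    truth = LandscapeTruth(coefficients=coef, intercept=cfg.intercept,
                           suitability=suit, config=cfg)
    return stack, occ, truth
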