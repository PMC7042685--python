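"""Multilocus SSR diversity, inbreeding, differentiation and AMOVA.

All estimators operate on a :class:`~landgen.types.GenotypeMatrix` and use
gene-copy counting: a diploid individual contributes two allele copies per
scored locus, missing genotypes contribute nothing.

Per-site statistics (the columns of a classic SSR diversity table):

* ``A``  — allelic richness, mean number of distinct alleles per locus;
* ``I``  — Shannon information index, ``-sum(p ln p)`` per locus;
* ``He`` — expected heterozygosity ``1 - sum(p^2)`` (Nei gene diversity;
  an optional ``2n/(2n-1)`` small-sample correction);
* ``Ho`` — observed fraction of heterozygous genotypes;
* ``Fis`` — multilocus inbreeding coefficient ``1 - mean(Ho)/mean(He)``
  (ratio of multilocus means, not a per-locus average of ratios).

Differentiation is Nei's ``F_ST = (H_T - H_S)/H_T`` with loci combined as a
ratio of sums, and a two-level AMOVA partitions squared inter-individual
allele-difference distances among and within populations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


class EstimatorError(ValueError):
    pass


# ----------------------------------------------------------------------
# Allele frequencies
# ----------------------------------------------------------------------

@dataclass
class LocusFrequencies:
    """Allele frequency table for one locus in one group of individuals."""

    alleles: np.ndarray          # sorted allele codes
    frequencies: np.ndarray      # same order, sums to 1
    n_copies: int                # 2 x non-missing individuals
    n_individuals: int           # non-missing individuals

    @property
    def scored(self) -> bool:
        return self.n_copies > 0


def _locus_frequencies(calls_l: np.ndarray) -> LocusFrequencies:
    copies = calls_l.ravel()
    copies = copies[copies != MISSING]
    if copies.size == 0:
        return LocusFrequencies(np.array([], dtype=np.int64),
                                np.array([]), 0, 0)
    alleles, counts = np.unique(copies, return_counts=True)
    return LocusFrequencies(
        alleles=alleles,
        frequencies=counts / copies.size,
        n_copies=int(copies.size),
        n_individuals=int(copies.size // 2),
    )


def allele_frequencies(
    G: GenotypeMatrix, by: str = "population"
) -> dict[str, list[LocusFrequencies]]:
    """Per-locus allele frequency tables, per population or pooled.

    Returns ``{group: [LocusFrequencies per locus]}``; with ``by="all"``
    the single group is named ``"all"``. Loci with no scored individuals
    in a group are returned unscored (``n_copies == 0``).
    """
    if by == "all":
        groups = {"all": np.arange(G.n_individuals)}
    elif by == "population":
        groups = {p: G.population_indices(p) for p in G.populations}
    else:
        raise ValueError(f"by must be 'population' or 'all', got {by!r}")
    out: dict[str, list[LocusFrequencies]] = {}
    for name, idx in groups.items():
        if idx.size == 0:
            raise EstimatorError(f"empty group {name!r}")
        out[name] = [
            _locus_frequencies(G.calls[idx, l, :]) for l in range(G.n_loci)
        ]
    return out


# ----------------------------------------------------------------------
# Site statistics
# ----------------------------------------------------------------------

@dataclass
class SiteStats:
    """Multilocus diversity and inbreeding estimates for one sample set."""

    population: str
    n: int
    A: float
    I: float
    He: float
    Ho: float
    Fis: float
    sd: dict[str, float] = field(default_factory=dict)
    per_locus: pd.DataFrame | None = None
    p_value_fis: float | None = None
    fis_defined: bool = True

    def as_row(self) -> dict[str, float]:
        row: dict[str, float] = {"population": self.population, "n": self.n}
        for k in ("A", "I", "He", "Ho", "Fis"):
            row[k] = getattr(self, k)
            row[f"sd_{k}"] = self.sd.get(k, np.nan)
        if self.p_value_fis is not None:
            row["p_value_fis"] = self.p_value_fis
        return row


def _per_locus_stats(
    calls: np.ndarray, unbiased: bool
) -> pd.DataFrame:
    """Per-locus A, I, He, Ho for a calls array of shape (n, L, 2)."""
    rows = []
    for l in range(calls.shape[1]):
        lf = _locus_frequencies(calls[:, l, :])
        if lf.n_individuals < 1:
            rows.append(dict(A=np.nan, I=np.nan, He=np.nan, Ho=np.nan,
                             n_scored=0))
            continue
        p = lf.frequencies
        he = 1.0 - float(np.sum(p ** 2))
        if unbiased and lf.n_copies > 1:
            he *= lf.n_copies / (lf.n_copies - 1)
        scored = calls[:, l, 0] != MISSING
        het = calls[scored, l, 0] != calls[scored, l, 1]
        rows.append(dict(
            A=float(len(lf.alleles)),
            I=float(-np.sum(p * np.log(p))),
            He=he,
            Ho=float(np.mean(het)),
            n_scored=int(scored.sum()),
        ))
    return pd.DataFrame(rows)


def site_stats(
    G: GenotypeMatrix,
    population: str | None = None,
    unbiased: bool = False,
    min_scored: int = 2,
) -> SiteStats:
    """Multilocus diversity estimates for one population (or the pool).

    Multilocus values are unweighted means over loci; ``sd`` is the standard
    deviation over loci (ddof=1). Loci with fewer than ``min_scored``
    genotyped individuals in the group are dropped from the multilocus
    means (and logged). ``Fis = 1 - mean(Ho)/mean(He)``.
    """
    if population is None:
        idx = np.arange(G.n_individuals)
        name = "all"
    else:
        idx = G.population_indices(population)
        name = population
    if idx.size < 2:
        raise EstimatorError(f"population {name!r} has fewer than 2 individuals")
    per = _per_locus_stats(G.calls[idx], unbiased=unbiased)
    ok = per["n_scored"] >= min_scored
    if not ok.all():
        dropped = [G.locus_names[l] for l in np.where(~ok)[0]]
        logger.warning("population %s: dropped loci with <%d scored "
                       "individuals: %s", name, min_scored, dropped)
    use = per[ok]
    if len(use) == 0:
        raise EstimatorError(f"population {name!r}: no usable loci")
    means = use[["A", "I", "He", "Ho"]].mean()
    sds = use[["A", "I", "He", "Ho"]].std(ddof=1)
    fis_defined = means["He"] > 0
    fis = float(1.0 - means["Ho"] / means["He"]) if fis_defined else np.nan
    if not fis_defined:
        logger.warning("population %s monomorphic at all loci: Fis undefined",
                       name)
    else:
        # per-locus Fis spread (loci with He>0) for the sd column
        with np.errstate(divide="ignore", invalid="ignore"):
            fis_l = 1.0 - use["Ho"] / use["He"]
        sd_fis = float(fis_l.replace([np.inf, -np.inf], np.nan).std(ddof=1))
    return SiteStats(
        population=name,
        n=int(idx.size),
        A=float(means["A"]),
        I=float(means["I"]),
        He=float(means["He"]),
        Ho=float(means["Ho"]),
        Fis=fis,
        sd={"A": float(sds["A"]), "I": float(sds["I"]),
            "He": float(sds["He"]), "Ho": float(sds["Ho"]),
            "Fis": sd_fis if fis_defined else np.nan},
        per_locus=per,
        fis_defined=bool(fis_defined),
    )


def stats_table(G: GenotypeMatrix, unbiased: bool = False) -> pd.DataFrame:
    """Diversity table with one row per population (n, A, I, He, Ho, Fis)."""
    rows = [site_stats(G, p, unbiased=unbiased).as_row() for p in G.populations]
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Fis permutation test
# ----------------------------------------------------------------------

def _fis_of_calls(calls: np.ndarray) -> float:
    per = _per_locus_stats(calls, unbiased=False)
    use = per[per["n_scored"] >= 1]
    he, ho = use["He"].mean(), use["Ho"].mean()
    return float(1.0 - ho / he) if he > 0 else np.nan


def fis_permutation_test(
    G: GenotypeMatrix,
    population: str,
    n_perm: int = 999,
    seed: int | None = None,
) -> float:
    """Two-sided permutation p-value for Fis != 0.

    The null is built by shuffling allele copies among individuals within
    the population, independently per locus — this destroys any heterozygote
    deficit or excess while preserving allele frequencies. p-values use the
    ``(1 + #{|Fis_perm| >= |Fis_obs|}) / (n_perm + 1)`` continuity rule, so
    ``n_perm = 0`` gives p = 1.
    """
    if n_perm < 99:
        logger.warning("n_perm=%d is low; p-value resolution is coarse", n_perm)
    idx = G.population_indices(population)
    calls = G.calls[idx].copy()
    obs = _fis_of_calls(calls)
    if np.isnan(obs):
        raise EstimatorError(f"Fis undefined for population {population!r}")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = calls.copy()
        for l in range(calls.shape[1]):
            scored = calls[:, l, 0] != MISSING
            copies = calls[scored, l, :].ravel()
            rng.shuffle(copies)
            perm[scored, l, :] = copies.reshape(-1, 2)
        if abs(_fis_of_calls(perm)) >= abs(obs) - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)


# ----------------------------------------------------------------------
# Nei F_ST
# ----------------------------------------------------------------------

@dataclass
class FstMatrix:
    """Pairwise Nei F_ST with per-population means.

    ``values`` is symmetric with zero diagonal; raw (possibly slightly
    negative) estimates are kept, and :meth:`display` truncates negatives
    to 0 for reporting.
    """

    populations: list[str]
    values: pd.DataFrame

    @property
    def per_population_mean(self) -> pd.Series:
        v = self.values.to_numpy(dtype=float).copy()
        np.fill_diagonal(v, np.nan)
        return pd.Series(np.nanmean(v, axis=1), index=self.populations)

    def display(self) -> pd.DataFrame:
        return self.values.clip(lower=0.0)


def _pair_fst(
    freqs_a: list[LocusFrequencies],
    freqs_b: list[LocusFrequencies],
    deme_correction: bool = True,
) -> float:
    """Nei F_ST for one population pair, ratio of sums over loci.

    Per locus ``H_S`` is the mean of the two within-population expected
    heterozygosities and ``H_T`` the expected heterozygosity of the pooled
    (mean) frequencies. With ``deme_correction`` the between-population
    gene diversity is rescaled by ``r/(r-1) = 2`` for the pair of demes
    (Nei's D_m), i.e. ``F_ST = D_m / (H_S + D_m)``; this removes the
    within-pair dilution of pooled H_T, so the estimator is centered on
    the Balding-Nichols F rather than on ``F/(2-F)``. Without it the raw
    pooled-H_T coefficient ``(H_T - H_S)/H_T`` is returned.
    """
    num = 0.0
    den = 0.0
    shared = 0
    for fa, fb in zip(freqs_a, freqs_b):
        if not (fa.scored and fb.scored):
            continue
        shared += 1
        alleles = np.union1d(fa.alleles, fb.alleles)
        pa = np.zeros(len(alleles))
        pb = np.zeros(len(alleles))
        pa[np.searchsorted(alleles, fa.alleles)] = fa.frequencies
        pb[np.searchsorted(alleles, fb.alleles)] = fb.frequencies
        hs = 0.5 * ((1 - np.sum(pa ** 2)) + (1 - np.sum(pb ** 2)))
        pbar = 0.5 * (pa + pb)
        ht = 1 - np.sum(pbar ** 2)
        if deme_correction:
            dm = 2.0 * (ht - hs)
            num += dm
            den += hs + dm
        else:
            num += ht - hs
            den += ht
    if shared == 0:
        return np.nan
    return num / den if den > 0 else 0.0


def pairwise_fst(G: GenotypeMatrix, deme_correction: bool = True) -> FstMatrix:
    """Pairwise Nei F_ST between all populations.

    ``F_ST = (H_T - H_S) / H_T`` per locus combined as a ratio of sums,
    with the two-deme correction on the between-population component by
    default (see :func:`_pair_fst`). Pairs with no locus scored in both
    populations get NaN.
    """
    pops = G.populations
    if len(pops) < 2:
        raise EstimatorError("pairwise F_ST needs at least 2 populations")
    freqs = allele_frequencies(G, by="population")
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for a, b in combinations(pops, 2):
        v = _pair_fst(freqs[a], freqs[b], deme_correction=deme_correction)
        if np.isnan(v):
            logger.warning("populations %s/%s share no scored locus", a, b)
        mat.loc[a, b] = mat.loc[b, a] = v
    return FstMatrix(populations=pops, values=mat)


# ----------------------------------------------------------------------
# AMOVA
# ----------------------------------------------------------------------

@dataclass
class AmovaResult:
    """Two-level AMOVA: among vs within populations."""

    sigma_among: float
    sigma_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    p_value: float | None
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    phi_defined: bool = True


def genetic_distance_matrix(G: GenotypeMatrix) -> np.ndarray:
    """Squared inter-individual distances: allele differences per locus.

    Per locus the distance between two diploid genotypes is the number of
    allele differences (0, 1 or 2 = two minus the size of the multiset
    intersection), summed over loci both individuals have scored and
    rescaled by ``n_loci / n_shared`` when loci are missing pairwise.
    """
    n, L, _ = G.calls.shape
    sorted_calls = np.sort(G.calls, axis=2)
    scored = G.calls[:, :, 0] != MISSING
    D = np.zeros((n, n))
    for i in range(n):
        a = sorted_calls[i]          # (L, 2)
        both = scored[i] & scored    # (n, L)
        # multiset intersection size for sorted pairs
        x0, x1 = a[:, 0], a[:, 1]
        y0, y1 = sorted_calls[:, :, 0], sorted_calls[:, :, 1]
        eq_both = (x0 == y0) & (x1 == y1)
        share_one = (
            (x0 == y0) | (x0 == y1) | (x1 == y0) | (x1 == y1)
        ) & ~eq_both
        d_l = np.where(eq_both, 0, np.where(share_one, 1, 2)).astype(float)
        n_shared = both.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(
                n_shared > 0,
                (d_l * both).sum(axis=1) * (L / np.maximum(n_shared, 1)),
                np.nan,
            )
        D[i] = d
    np.fill_diagonal(D, 0.0)
    return D


def _amova_components(D: np.ndarray, labels: np.ndarray) -> tuple[float, float, float, float, int, int]:
    """Variance components from a squared-distance matrix and group labels."""
    n = len(labels)
    groups = np.unique(labels)
    P = len(groups)
    iu = np.triu_indices(n, k=1)
    ss_total = float(np.nansum(D[iu])) / n
    ss_within = 0.0
    sizes = []
    for g in groups:
        idx = np.where(labels == g)[0]
        sizes.append(len(idx))
        if len(idx) > 1:
            sub = D[np.ix_(idx, idx)]
            ss_within += float(np.nansum(sub[np.triu_indices(len(idx), k=1)])) / len(idx)
    ss_among = ss_total - ss_within
    df_among = P - 1
    df_within = n - P
    sizes = np.asarray(sizes, dtype=float)
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    sigma_within = ms_within
    if df_among > 0:
        ms_among = ss_among / df_among
        n_bar = (n - np.sum(sizes ** 2) / n) / df_among
        sigma_among = (ms_among - ms_within) / n_bar if n_bar > 0 else 0.0
    else:
        sigma_among = 0.0
    return sigma_among, sigma_within, ss_among, ss_within, df_among, df_within


def amova(
    G: GenotypeMatrix, n_perm: int = 999, seed: int | None = None
) -> AmovaResult:
    """Two-level AMOVA with a permutation test for Phi_ST.

    Individuals are permuted among populations to build the null for
    ``Phi_ST = sigma^2_a / (sigma^2_a + sigma^2_b)``. Percentages are the
    components as a share of their (possibly negative-clipped) total and
    always sum to 100.
    """
    pops = np.asarray(G.population_labels)
    D = genetic_distance_matrix(G)
    s_a, s_w, ss_a, ss_w, df_a, df_w = _amova_components(D, pops)
    total = s_a + s_w
    if total <= 0:
        logger.warning("all individuals identical: AMOVA components are zero")
        return AmovaResult(0.0, 0.0, 0.0, 100.0, np.nan, None,
                           df_a, df_w, ss_a, ss_w, phi_defined=False)
    phi = s_a / total
    pct_a, pct_w = 100.0 * s_a / total, 100.0 * s_w / total
    p_value = None
    if n_perm > 0 and len(np.unique(pops)) > 1:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(pops)
            pa, pw, *_ = _amova_components(D, perm)
            tot = pa + pw
            phi_p = pa / tot if tot > 0 else 0.0
            if phi_p >= phi - 1e-12:
                hits += 1
        p_value = (1 + hits) / (n_perm + 1)
    return AmovaResult(
        sigma_among=s_a, sigma_within=s_w,
        pct_among=pct_a, pct_within=pct_w,
        phi_st=phi, p_value=p_value,
        df_among=df_a, df_within=df_w,
        ss_among=ss_a, ss_within=ss_w,
    )
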