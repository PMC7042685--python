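"""Admixture-model ancestry estimation and Evanno delta-K selection.

The model: each individual ``i`` draws each allele copy from one of ``K``
clusters according to its ancestry vector ``Q_i`` (rows of Q sum to 1), and
each cluster ``k`` has its own allele frequencies ``P_k`` per locus. The
log-likelihood is::

    L = sum_i sum_l sum_{copies c} log sum_k Q_ik P_{k, l, a(i,l,c)}

Rather than MCMC posterior sampling, the likelihood is maximized directly
by expectation-maximization with multiple seeded restarts; per-restart
log-likelihoods then feed the Evanno delta-K table exactly as per-run
``Ln P(D)`` values would. A small Dirichlet prior (Laplace smoothing) on
the cluster allele frequencies prevents zero-frequency lock-in; EM
monotonically increases the corresponding penalized log-likelihood.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .types import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class AdmixtureFit:
    """One converged EM run at a given K."""

    K: int
    Q: np.ndarray                    # (n, K) ancestry proportions
    P: np.ndarray                    # (K, L, A_max) cluster allele freqs
    loglik: float                    # data log-likelihood at the optimum
    objective_path: np.ndarray       # penalized objective per iteration
    loglik_path: np.ndarray          # data log-likelihood per iteration
    n_iter: int
    converged: bool
    seed: int | None
    replicate: int = 0
    allele_index: list[np.ndarray] = field(default_factory=list)
    n_alleles: np.ndarray | None = None


def _encode(G: GenotypeMatrix) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    """Map allele codes to dense per-locus indices; -1 marks missing."""
    n, L, _ = G.calls.shape
    codes = np.full((n, L, 2), -1, dtype=np.int64)
    allele_index: list[np.ndarray] = []
    n_alleles = np.zeros(L, dtype=int)
    for l in range(L):
        col = G.calls[:, l, :]
        alleles = np.unique(col[col != MISSING])
        allele_index.append(alleles)
        n_alleles[l] = len(alleles)
        scored = col[:, 0] != MISSING
        codes[scored, l, :] = np.searchsorted(alleles, col[scored])
    return codes, allele_index, n_alleles


def _loglik_terms(Q: np.ndarray, P: np.ndarray, codes: np.ndarray):
    """Per-copy mixture densities and responsibilities.

    Returns (denom, resp) with shapes (n, L, 2) and (K, n, L, 2); missing
    copies have denom 1 and resp 0.
    """
    n, L, _ = codes.shape
    K = Q.shape[1]
    safe = np.maximum(codes, 0)
    lidx = np.arange(L)[None, :, None]
    # Pg[k, i, l, s] = P[k, l, codes[i, l, s]]
    Pg = P[:, lidx, safe]                      # (K, n, L, 2)
    w = Q.T[:, :, None, None] * Pg             # (K, n, L, 2)
    denom = w.sum(axis=0)                      # (n, L, 2)
    valid = codes >= 0
    denom = np.where(valid, denom, 1.0)
    resp = np.where(valid[None], w / np.maximum(denom[None], 1e-300), 0.0)
    return denom, resp, valid


def fit_admixture(
    G: GenotypeMatrix,
    K: int,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    alpha: float = 0.01,
) -> AdmixtureFit:
    """EM maximization of the admixture log-likelihood for one start.

    ``alpha`` is the Laplace smoothing pseudo-count added to cluster allele
    tallies in the M-step (a symmetric Dirichlet prior on P). Convergence
    is declared when the penalized objective improves by less than ``tol``.
    Missing genotypes contribute nothing to likelihood or updates.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    codes, allele_index, n_alleles = _encode(G)
    n, L, _ = codes.shape
    A_max = int(n_alleles.max())
    if K > 1 and K > int(n_alleles.sum()):
        logger.warning("K=%d exceeds the distinct-allele budget; "
                       "degenerate clusters likely", K)
    rng = np.random.default_rng(seed)

    # valid-allele mask per locus for normalization and the prior term
    amask = np.zeros((L, A_max), dtype=bool)
    for l in range(L):
        amask[l, : n_alleles[l]] = True

    Q = rng.dirichlet(np.ones(K), size=n)
    P = np.zeros((K, L, A_max))
    for l in range(L):
        P[:, l, : n_alleles[l]] = rng.dirichlet(np.ones(n_alleles[l]), size=K)

    def objective(denom: np.ndarray, valid: np.ndarray, P: np.ndarray) -> tuple[float, float]:
        ll = float(np.log(np.maximum(denom, 1e-300))[valid].sum())
        prior = float(alpha * np.log(np.maximum(P, 1e-300))[:, amask].sum())
        return ll, ll + prior

    obj_path = []
    ll_path = []
    prev = -np.inf
    converged = False
    n_copies = np.maximum((codes[:, :, 0] >= 0).sum(axis=1) * 2, 1)  # per individual
    for it in range(max_iter):
        denom, resp, valid = _loglik_terms(Q, P, codes)
        ll, obj = objective(denom, valid, P)
        ll_path.append(ll)
        obj_path.append(obj)
        if obj - prev < tol and it > 0:
            converged = True
            break
        prev = obj
        # M-step
        Q = resp.sum(axis=(2, 3)).T / n_copies[:, None]     # (n, K)
        Q = Q / Q.sum(axis=1, keepdims=True)
        flat_idx = (np.arange(L)[None, :, None] * A_max
                    + np.maximum(codes, 0))            # (n, L, 2)
        P_new = np.stack([
            np.bincount(flat_idx[valid], weights=resp[k][valid],
                        minlength=L * A_max).reshape(L, A_max)
            for k in range(K)
        ])
        P_new += alpha * amask[None, :, :]
        P = P_new / np.maximum(P_new.sum(axis=2, keepdims=True), 1e-300)
        P[:, ~amask] = 0.0

    denom, _, valid = _loglik_terms(Q, P, codes)
    ll, obj = objective(denom, valid, P)
    ll_path.append(ll)
    obj_path.append(obj)
    return AdmixtureFit(
        K=K, Q=Q, P=P, loglik=ll,
        objective_path=np.asarray(obj_path),
        loglik_path=np.asarray(ll_path),
        n_iter=len(obj_path) - 1,
        converged=converged,
        seed=seed,
        allele_index=allele_index,
        n_alleles=n_alleles,
    )


def fit_admixture_restarts(
    G: GenotypeMatrix,
    K: int,
    restarts: int = 10,
    seed: int | None = None,
    **kwargs,
) -> list[AdmixtureFit]:
    """Independent seeded EM runs at one K (best fit = highest loglik)."""
    rng = np.random.default_rng(seed)
    fits = []
    for r in range(restarts):
        fit = fit_admixture(G, K, seed=int(rng.integers(2 ** 31)), **kwargs)
        fit.replicate = r
        fits.append(fit)
    return fits


def best_fit(fits: list[AdmixtureFit]) -> AdmixtureFit:
    return max(fits, key=lambda f: f.loglik)


# ----------------------------------------------------------------------
# Evanno delta-K
# ----------------------------------------------------------------------

@dataclass
class DeltaKTable:
    """Evanno statistics per K plus the selected K."""

    table: pd.DataFrame  # K, n_reps, mean_loglik, sd_loglik, lprime, lsecond, delta_k
    best_k: int | None


def evanno_delta_k(logliks: pd.DataFrame | dict[int, list[float]]) -> DeltaKTable:
    """Evanno delta-K from a table of per-replicate log-likelihoods.

    Input: either ``{K: [loglik per replicate]}`` or a DataFrame with
    columns ``K`` and ``loglik``. With mean log-likelihood ``L(K)``:
    ``L'(K) = L(K) - L(K-1)``, ``L''(K) = L'(K+1) - L'(K)`` and
    ``delta_K = |L''(K)| / sd(L(K))``, defined for interior K only.
    The selected K is the argmax; ties break toward the smallest K.
    """
    if isinstance(logliks, pd.DataFrame):
        groups = {int(k): g["loglik"].to_numpy(float)
                  for k, g in logliks.groupby("K")}
    else:
        groups = {int(k): np.asarray(v, dtype=float) for k, v in logliks.items()}
    ks = sorted(groups)
    if len(ks) < 3:
        raise ValueError("delta-K needs at least 3 consecutive K values")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("K values must be consecutive")
    mean = {k: float(np.mean(groups[k])) for k in ks}
    sd = {k: float(np.std(groups[k], ddof=1)) if len(groups[k]) > 1 else 0.0
          for k in ks}
    rows = []
    for k in ks:
        lp = mean[k] - mean[k - 1] if k - 1 in mean else np.nan
        ls = (mean[k + 1] - 2 * mean[k] + mean[k - 1]
              if (k - 1 in mean and k + 1 in mean) else np.nan)
        if not np.isnan(ls):
            if sd[k] > 0:
                dk = abs(ls) / sd[k]
            else:
                dk = np.nan
                logger.warning("sd of loglik at K=%d is 0: delta-K undefined", k)
        else:
            dk = np.nan
        rows.append(dict(K=k, n_reps=len(groups[k]), mean_loglik=mean[k],
                         sd_loglik=sd[k], lprime=lp, lsecond=ls, delta_k=dk))
    df = pd.DataFrame(rows)
    defined = df.dropna(subset=["delta_k"])
    best = int(defined.loc[defined["delta_k"].idxmax(), "K"]) if len(defined) else None
    if len(defined):
        top = defined[np.isclose(defined["delta_k"], defined["delta_k"].max())]
        best = int(top["K"].min())  # parsimony tie-break
    return DeltaKTable(table=df, best_k=best)


def read_structure_logliks(paths: list[str | Path]) -> pd.DataFrame:
    """Extract (K, loglik) from STRUCTURE results files.

    Looks for the ``Estimated Ln Prob of Data`` line and the run's K, so
    real STRUCTURE output can feed :func:`evanno_delta_k` directly.
    """
    rows = []
    ll_re = re.compile(r"Estimated Ln Prob of Data\s*=\s*(-?[\d.]+)")
    k_re = re.compile(r"(\d+)\s+populations assumed")
    for path in paths:
        text = Path(path).read_text()
        ll = ll_re.search(text)
        k = k_re.search(text)
        if ll and k:
            rows.append(dict(K=int(k.group(1)), loglik=float(ll.group(1)),
                             file=str(path)))
        else:
            logger.warning("%s: no loglik/K found, skipped", path)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Replicate alignment (label switching)
# ----------------------------------------------------------------------

def align_replicates(fits: list[AdmixtureFit]) -> tuple[list[np.ndarray], np.ndarray]:
    """Align cluster labels across replicates; return aligned Qs and mean Q.

    The best-loglik replicate is the reference; each other replicate's
    columns are permuted by the Hungarian assignment maximizing the summed
    inner product between Q columns (equivalent to minimizing Frobenius
    distance for column permutations).
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to align")
    K = fits[0].K
    n = fits[0].Q.shape[0]
    for f in fits:
        if f.K != K or f.Q.shape[0] != n:
            raise ValueError("fits must share K and the individual set")
    ref = best_fit(fits)
    aligned = []
    for f in fits:
        cost = -(ref.Q.T @ f.Q)          # (K, K)
        _, perm = linear_sum_assignment(cost)
        aligned.append(f.Q[:, perm])
    return aligned, np.mean(aligned, axis=0)
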