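"""Ensemble habitat-suitability modeling with calibrated AUC.

The framework: presence points plus background points sampled inside a
buffered convex hull; collinear predictors pruned by iterative VIF; base
suitability models (a BIOCLIM-style percentile envelope and an
L2-regularized logistic regression ship, any scikit-learn-style learner
can be registered) evaluated by *calibrated AUC* against a geographic null
model to guard against spatial sorting bias; models not significantly
better than the null (one-sided Mann-Whitney over iterations) are dropped;
all ensemble combinations containing an anchor model are scored and the
best cAUC-weighted ensemble retained; suitability maps are binarized at
the maximum training sensitivity+specificity threshold, and multi-scenario
projections are summarized by optimistic (any) / pessimistic (majority)
consensus.

Calibrated AUC corrects the raw AUC for the inflation a purely geographic
model achieves on spatially clustered data: each test presence is matched
to the background point with the most similar distance-to-nearest-training-
presence, and ``cAUC = AUC_model - (AUC_null - 0.5)`` on the matched set,
capped into [0, 1]. The null model evaluated against itself yields exactly
0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Protocol

import numpy as np
from scipy.stats import mannwhitneyu, rankdata
from shapely.geometry import MultiPoint, Point
from sklearn.linear_model import LogisticRegression

from .raster import Grid, Raster
from .types import OccurrenceSet

logger = logging.getLogger(__name__)

#: soil-depth weights for 0-5, 5-15, 15-30, 30-60, 60-100 cm layers
SOIL_DEPTH_WEIGHTS = (0.05, 0.10, 0.15, 0.30, 0.40)


class SdmError(ValueError):
    pass


# ----------------------------------------------------------------------
# Environmental stack
# ----------------------------------------------------------------------

@dataclass
class EnvStack:
    """Named co-registered raster layers sharing one grid geometry."""

    grid: Grid
    layers: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.grid.shape:
                raise SdmError(f"layer {name!r} shape {arr.shape} != grid "
                               f"{self.grid.shape}")
            self.layers[name] = arr

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def mask(self) -> np.ndarray:
        """True where every layer holds data (no-data masks unioned)."""
        m = np.ones(self.grid.shape, dtype=bool)
        for arr in self.layers.values():
            m &= ~np.isnan(arr)
        return m

    def features_at(self, lon: np.ndarray, lat: np.ndarray,
                    names: list[str] | None = None) -> np.ndarray:
        rows, cols = self.grid.index_of(lon, lat)
        names = names or self.names
        return np.column_stack([self.layers[n][rows, cols] for n in names])

    def subset(self, names: list[str]) -> "EnvStack":
        return EnvStack(grid=self.grid,
                        layers={n: self.layers[n] for n in names})


def soil_depth_mean(layers: list[np.ndarray]) -> np.ndarray:
    """Thickness-weighted 0-100 cm mean of five soil-depth layers.

    Layers are for 0-5, 5-15, 15-30, 30-60 and 60-100 cm; weights are the
    layer thicknesses (0.05, 0.1, 0.15, 0.3, 0.4). A cell missing any
    depth is no-data in the result.
    """
    if len(layers) != 5:
        raise SdmError(f"expected 5 depth layers, got {len(layers)}")
    arrs = [np.asarray(a, dtype=float) for a in layers]
    out = sum(w * a for w, a in zip(SOIL_DEPTH_WEIGHTS, arrs))
    bad = np.zeros_like(out, dtype=bool)
    for a in arrs:
        bad |= np.isnan(a)
    out = np.asarray(out, dtype=float)
    out[bad] = np.nan
    return out


# ----------------------------------------------------------------------
# Background sampling
# ----------------------------------------------------------------------

def background_region(presences: OccurrenceSet) -> "object":
    """Convex hull of presences buffered by 10% of its largest axis."""
    pts = presences.points
    if len(pts) < 3:
        raise SdmError("need at least 3 presence points for a hull")
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if hull.geom_type != "Polygon":
        raise SdmError("presences are collinear; hull is degenerate")
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    largest_axis = float(d.max())
    return hull.buffer(0.10 * largest_axis)


def sample_background(
    presences: OccurrenceSet,
    grid: Grid,
    max_n: int = 10_000,
    seed: int | None = None,
    exclude_presence_cells: bool = True,
    mask: np.ndarray | None = None,
) -> OccurrenceSet:
    """Random background points: at most one per grid cell, uniform over
    the buffered-hull region, presence cells excluded."""
    region = background_region(presences)
    lon, lat = grid.centers()
    flat_lon, flat_lat = lon.ravel(), lat.ravel()
    ok = np.ones(flat_lon.size, dtype=bool)
    if mask is not None:
        ok &= mask.ravel()
    minx, miny, maxx, maxy = region.bounds
    ok &= (flat_lon >= minx) & (flat_lon <= maxx)
    ok &= (flat_lat >= miny) & (flat_lat <= maxy)
    cand = np.where(ok)[0]
    inside = np.array([region.contains(Point(flat_lon[i], flat_lat[i]))
                       or region.touches(Point(flat_lon[i], flat_lat[i]))
                       for i in cand])
    cand = cand[inside]
    if exclude_presence_cells:
        pr, pc = grid.index_of(presences.points[:, 0], presences.points[:, 1])
        pres_flat = set(pr * grid.ncols + pc)
        cand = np.array([i for i in cand if i not in pres_flat], dtype=int)
    rng = np.random.default_rng(seed)
    take = min(max_n, cand.size)
    pick = rng.choice(cand, size=take, replace=False)
    return OccurrenceSet(
        points=np.column_stack([flat_lon[pick], flat_lat[pick]]),
        sources=["background"] * take,
    )


# ----------------------------------------------------------------------
# VIF pruning
# ----------------------------------------------------------------------

def _vif(X: np.ndarray, j: int) -> float:
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    A = np.column_stack([np.ones(len(others)), others])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return np.inf
    r2 = 1.0 - ss_res / ss_tot
    return np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)


def vif_prune(
    stack: EnvStack | None,
    threshold: float = 5.0,
    samples: np.ndarray | None = None,
    names: list[str] | None = None,
) -> list[str]:
    """Iteratively drop the layer with the highest VIF until all < threshold.

    ``samples`` is an (n, p) matrix of layer values at sample cells; if
    omitted it is taken from all valid cells of the stack. Perfectly
    collinear layers have infinite VIF and are dropped first (the later
    layer in stack order, keeping the earlier one — deterministic).
    """
    if samples is None:
        if stack is None:
            raise SdmError("need a stack or a samples matrix")
        m = stack.mask()
        samples = np.column_stack([stack.layers[n][m] for n in stack.names])
        names = stack.names
    if names is None:
        names = [f"x{j}" for j in range(samples.shape[1])]
    keep = list(range(samples.shape[1]))
    while len(keep) > 1:
        vifs = np.array([_vif(samples[:, keep], jj) for jj in range(len(keep))])
        worst = int(np.argmax(vifs))  # first max wins: earlier dup survives? see below
        # drop the LAST among ties so the earliest layer is preferred
        ties = np.where(np.isclose(vifs, vifs[worst]) | (np.isinf(vifs) & np.isinf(vifs[worst])))[0]
        worst = int(ties.max()) if np.isinf(vifs[worst]) else worst
        if vifs[worst] < threshold:
            break
        logger.info("VIF prune: dropping %s (VIF=%.3g)", names[keep[worst]],
                    vifs[worst])
        keep.pop(worst)
    return [names[j] for j in keep]


# ----------------------------------------------------------------------
# Base models
# ----------------------------------------------------------------------

class SuitabilityModel(Protocol):
    name: str
    def fit(self, X_pres: np.ndarray, X_back: np.ndarray) -> "SuitabilityModel": ...
    def predict(self, X: np.ndarray) -> np.ndarray: ...


class EnvelopeModel:
    """BIOCLIM-style percentile envelope.

    Suitability of a cell is the fraction of predictors whose value lies
    within the [p_lo, p_hi] percentile envelope of the presence values.
    """

    name = "envelope"

    def __init__(self, p_lo: float = 5.0, p_hi: float = 95.0):
        self.p_lo, self.p_hi = p_lo, p_hi
        self.lo: np.ndarray | None = None
        self.hi: np.ndarray | None = None

    def fit(self, X_pres: np.ndarray, X_back: np.ndarray) -> "EnvelopeModel":
        self.lo = np.percentile(X_pres, self.p_lo, axis=0)
        self.hi = np.percentile(X_pres, self.p_hi, axis=0)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        inside = (X >= self.lo) & (X <= self.hi)
        return inside.mean(axis=1)


class RegularizedLogisticModel:
    """L2-regularized presence/background logistic regression on
    standardized features."""

    name = "logistic"

    def __init__(self, C: float = 1.0, seed: int | None = 0):
        self.C = C
        self.seed = seed
        self._clf: LogisticRegression | None = None
        self._mu: np.ndarray | None = None
        self._sd: np.ndarray | None = None

    def fit(self, X_pres: np.ndarray, X_back: np.ndarray) -> "RegularizedLogisticModel":
        X = np.vstack([X_pres, X_back])
        y = np.r_[np.ones(len(X_pres)), np.zeros(len(X_back))]
        self._mu = X.mean(axis=0)
        self._sd = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        Z = (X - self._mu) / self._sd
        self._clf = LogisticRegression(C=self.C, max_iter=1000,
                                       random_state=self.seed)
        self._clf.fit(Z, y)
        return self

    @property
    def coef_(self) -> np.ndarray:
        return self._clf.coef_[0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self._mu) / self._sd
        return self._clf.predict_proba(Z)[:, 1]


MODEL_REGISTRY: dict[str, Callable[..., SuitabilityModel]] = {
    "envelope": EnvelopeModel,
    "logistic": RegularizedLogisticModel,
}


def register_model(name: str, factory: Callable[..., SuitabilityModel]) -> None:
    """Register a user-supplied suitability learner under ``name``."""
    MODEL_REGISTRY[name] = factory


def fit_base_model(
    name: str,
    presences: OccurrenceSet,
    background: OccurrenceSet,
    stack: EnvStack,
    seed: int | None = 0,
    feature_names: list[str] | None = None,
) -> SuitabilityModel:
    """Fit a registered base model on presence/background features."""
    if name not in MODEL_REGISTRY:
        raise SdmError(f"unknown model {name!r}; registered: "
                       f"{sorted(MODEL_REGISTRY)}")
    if len(presences) < 10:
        raise SdmError("need at least 10 presences to fit a base model")
    factory = MODEL_REGISTRY[name]
    try:
        model = factory(seed=seed)
    except TypeError:
        model = factory()
    Xp = stack.features_at(presences.points[:, 0], presences.points[:, 1],
                           feature_names)
    Xb = stack.features_at(background.points[:, 0], background.points[:, 1],
                           feature_names)
    return model.fit(Xp, Xb)


# ----------------------------------------------------------------------
# Geographic null model and AUC
# ----------------------------------------------------------------------

def _nearest_presence_distance(points: np.ndarray, train: np.ndarray) -> np.ndarray:
    d = np.sqrt(((points[:, None, :] - train[None, :, :]) ** 2).sum(-1))
    return d.min(axis=1)


class GeographicNullModel:
    """Distance-based null: suitability decreases with distance to the
    nearest training presence, rank-normalized over the model extent.

    The model sees no environmental data at all; any AUC above 0.5 it
    achieves on a test set measures spatial sorting bias, not ecology.
    """

    name = "geographic_null"

    def __init__(self, train_presences: np.ndarray, grid: Grid):
        if len(train_presences) < 1:
            raise SdmError("need at least 1 training presence")
        self.train = np.asarray(train_presences, dtype=float)
        lon, lat = grid.centers()
        cells = np.column_stack([lon.ravel(), lat.ravel()])
        self._ref = np.sort(_nearest_presence_distance(cells, self.train))

    def score_points(self, points: np.ndarray) -> np.ndarray:
        d = _nearest_presence_distance(np.asarray(points, float), self.train)
        # 1 at distance 0, 0 at/after the farthest cell in the extent
        n = len(self._ref)
        rank = np.searchsorted(self._ref, d, side="left")
        return 1.0 - rank / max(n - 1, 1)


def auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney), ties counted one half."""
    pos = np.asarray(pos_scores, float)
    neg = np.asarray(neg_scores, float)
    if pos.size == 0 or neg.size == 0:
        raise SdmError("AUC needs both positive and negative scores")
    ranks = rankdata(np.r_[pos, neg])
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


# ----------------------------------------------------------------------
# Calibrated AUC
# ----------------------------------------------------------------------

def _pwd_match(
    test_pres: np.ndarray,
    background: np.ndarray,
    train_pres: np.ndarray,
) -> np.ndarray:
    """Pairwise-distance background matching (greedy, without replacement).

    Each test presence is matched with the unused background point whose
    distance-to-nearest-training-presence is closest to the presence's
    own; presences are processed in increasing order of that distance, so
    the procedure is deterministic.
    """
    dp = _nearest_presence_distance(test_pres, train_pres)
    db = _nearest_presence_distance(background, train_pres)
    order = np.argsort(dp, kind="stable")
    free = np.ones(len(background), dtype=bool)
    matched = np.full(len(test_pres), -1, dtype=int)
    for i in order:
        idx = np.where(free)[0]
        if idx.size == 0:
            raise SdmError("insufficient background points for matching")
        j = idx[np.argmin(np.abs(db[idx] - dp[i]))]
        matched[i] = j
        free[j] = False
    return matched


@dataclass
class CaucResult:
    cauc: list[float]
    auc_model: list[float]
    auc_null: list[float]
    cauc_uncapped: list[float]


def calibrated_auc(
    model: SuitabilityModel,
    presences: OccurrenceSet,
    background: OccurrenceSet,
    stack: EnvStack,
    grid: Grid | None = None,
    k_folds: int = 4,
    seed: int | None = 0,
    feature_names: list[str] | None = None,
    refit: bool = True,
) -> CaucResult:
    """Cross-validated calibrated AUC for one model.

    Per fold: the model is refit on training presences (vs the full
    background), the geographic null is built from training presences,
    test presences are matched to distance-similar background points, and
    ``cAUC = AUC_model - (AUC_null - 0.5)`` on the matched evaluation set,
    capped into [0, 1] (the uncapped value is kept alongside).
    """
    if k_folds < 2:
        raise SdmError("k_folds must be >= 2")
    grid = grid or stack.grid
    rng = np.random.default_rng(seed)
    n = len(presences)
    order = rng.permutation(n)
    folds = np.array_split(order, k_folds)
    res = CaucResult([], [], [], [])
    Xb = stack.features_at(background.points[:, 0], background.points[:, 1],
                           feature_names)
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(order, test_idx)
        if test_idx.size == 0 or train_idx.size == 0:
            continue
        train_pts = presences.points[train_idx]
        test_pts = presences.points[test_idx]
        if len(background) < len(test_pts):
            logger.warning("fold %d skipped: %d background for %d test "
                           "presences", f, len(background), len(test_pts))
            continue
        null = GeographicNullModel(train_pts, grid)
        if isinstance(model, GeographicNullModel):
            # the null is itself refit per fold, making the correction an
            # identity: cAUC = AUC - (AUC - 0.5) = 0.5 exactly
            fold_model = null
        elif refit:
            Xp_train = stack.features_at(train_pts[:, 0], train_pts[:, 1],
                                         feature_names)
            fold_model = type(model)() if not hasattr(model, "seed") else type(model)(seed=seed)
            fold_model.fit(Xp_train, Xb)
        else:
            fold_model = model
        match = _pwd_match(test_pts, background.points, train_pts)
        eval_back = background.points[match]
        if isinstance(fold_model, GeographicNullModel):
            s_pos = fold_model.score_points(test_pts)
            s_neg = fold_model.score_points(eval_back)
        else:
            s_pos = fold_model.predict(
                stack.features_at(test_pts[:, 0], test_pts[:, 1], feature_names))
            s_neg = fold_model.predict(
                stack.features_at(eval_back[:, 0], eval_back[:, 1], feature_names))
        a_model = auc(s_pos, s_neg)
        a_null = auc(null.score_points(test_pts), null.score_points(eval_back))
        raw = a_model - (a_null - 0.5)
        res.auc_model.append(a_model)
        res.auc_null.append(a_null)
        res.cauc_uncapped.append(raw)
        res.cauc.append(float(np.clip(raw, 0.0, 1.0)))
    return res


# ----------------------------------------------------------------------
# Model retention (Mann-Whitney vs null)
# ----------------------------------------------------------------------

def mann_whitney_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic of x over y, ties counted one half."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    ranks = rankdata(np.r_[x, y])
    return float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0)


def retain_models(
    model_caucs: dict[str, np.ndarray],
    null_caucs: np.ndarray,
    alpha: float = 0.05,
) -> list[str]:
    """Keep models whose cAUC iterations beat the null's (one-sided
    Mann-Whitney, p < alpha). Identical samples give p = 1 (not retained)."""
    retained = []
    null_caucs = np.asarray(null_caucs, float)
    for name, vals in model_caucs.items():
        vals = np.asarray(vals, float)
        if np.allclose(vals, vals[0]) and np.allclose(null_caucs, vals[0]):
            p = 1.0  # every observation tied: no evidence either way
        else:
            p = float(mannwhitneyu(vals, null_caucs, alternative="greater").pvalue)
        if p < alpha:
            retained.append(name)
        logger.info("retention: %s p=%.4g %s", name, p,
                    "retained" if p < alpha else "dropped")
    return retained


# ----------------------------------------------------------------------
# Ensembles
# ----------------------------------------------------------------------

@dataclass
class EnsembleModel:
    """cAUC-weighted average of member suitability models."""

    members: list[str]
    weights: np.ndarray              # normalized, sum 1
    models: dict[str, SuitabilityModel]
    anchor: str
    cauc: float = np.nan
    threshold: float | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        preds = np.column_stack([self.models[m].predict(X) for m in self.members])
        return preds @ self.weights


def enumerate_anchored_subsets(members: list[str], anchor: str) -> list[tuple[str, ...]]:
    """All subsets of ``members`` containing ``anchor`` (2^(m-1) of them)."""
    if anchor not in members:
        raise SdmError(f"anchor {anchor!r} not among retained models")
    others = [m for m in members if m != anchor]
    if len(members) > 16:
        raise SdmError(f"{len(members)} retained models imply "
                       f"2^{len(members) - 1} combinations; pre-filter first")
    out = []
    for r in range(len(others) + 1):
        for combo in combinations(others, r):
            out.append(tuple([anchor, *combo]))
    return out


def ensemble_search(
    retained: dict[str, SuitabilityModel],
    mean_caucs: dict[str, float],
    anchor: str,
    presences: OccurrenceSet,
    background: OccurrenceSet,
    stack: EnvStack,
    k_folds: int = 4,
    seed: int | None = 0,
    feature_names: list[str] | None = None,
) -> tuple[EnsembleModel, dict[tuple[str, ...], float]]:
    """Exhaustive anchored ensemble search scored by cross-validated cAUC.

    Every subset of the retained models containing the anchor is formed as
    the weighted mean of member predictions (weights = mean cAUC,
    normalized) and scored on the same folds; the argmax ensemble is
    returned along with the full score table. Per-fold member scores are
    computed once, so the 2^(m-1) combinations cost only weighted sums.
    """
    names = list(retained)
    combos = enumerate_anchored_subsets(names, anchor)
    grid = stack.grid
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(presences))
    folds = np.array_split(order, k_folds)

    # per-fold evaluation sets and member scores, computed once
    fold_scores: list[dict[str, tuple[np.ndarray, np.ndarray]]] = []
    fold_null_corr: list[float] = []
    Xb_all = stack.features_at(background.points[:, 0], background.points[:, 1],
                               feature_names)
    for test_idx in folds:
        train_idx = np.setdiff1d(order, test_idx)
        if test_idx.size == 0 or train_idx.size == 0:
            continue
        train_pts = presences.points[train_idx]
        test_pts = presences.points[test_idx]
        null = GeographicNullModel(train_pts, grid)
        match = _pwd_match(test_pts, background.points, train_pts)
        eval_back = background.points[match]
        Xp = stack.features_at(test_pts[:, 0], test_pts[:, 1], feature_names)
        Xn = stack.features_at(eval_back[:, 0], eval_back[:, 1], feature_names)
        scores = {}
        for name in names:
            m = retained[name]
            scores[name] = (m.predict(Xp), m.predict(Xn))
        fold_scores.append(scores)
        a_null = auc(null.score_points(test_pts), null.score_points(eval_back))
        fold_null_corr.append(a_null - 0.5)

    table: dict[tuple[str, ...], float] = {}
    for combo in combos:
        w = np.array([max(mean_caucs[m], 1e-12) for m in combo])
        w = w / w.sum()
        caucs = []
        for scores, corr in zip(fold_scores, fold_null_corr):
            s_pos = sum(wi * scores[m][0] for wi, m in zip(w, combo))
            s_neg = sum(wi * scores[m][1] for wi, m in zip(w, combo))
            caucs.append(float(np.clip(auc(s_pos, s_neg) - corr, 0.0, 1.0)))
        table[combo] = float(np.mean(caucs))
    best_combo = max(table, key=lambda c: (table[c], -len(c)))
    w = np.array([max(mean_caucs[m], 1e-12) for m in best_combo])
    w = w / w.sum()
    best = EnsembleModel(
        members=list(best_combo), weights=w,
        models={m: retained[m] for m in best_combo},
        anchor=anchor, cauc=table[best_combo],
    )
    return best, table


# ----------------------------------------------------------------------
# Thresholding, projection, consensus
# ----------------------------------------------------------------------

def threshold_max_sens_spec(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Score cutoff maximizing sensitivity + specificity on training data.

    A cell is suitable when ``score >= threshold``. Candidates are the
    observed scores; ties break toward the lower threshold.
    """
    pos = np.asarray(pos_scores, float)
    neg = np.asarray(neg_scores, float)
    cands = np.unique(np.r_[pos, neg])
    if cands.size == 1:
        logger.warning("degenerate scores: threshold = %g", cands[0])
        return float(cands[0])
    best_t, best_v = None, -np.inf
    for t in cands:
        sens = float(np.mean(pos >= t))
        spec = float(np.mean(neg < t))
        v = sens + spec
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    return float(best_t)


def predict_raster(model: SuitabilityModel, stack: EnvStack,
                   feature_names: list[str] | None = None) -> Raster:
    """Apply a suitability model to every valid cell of a stack."""
    m = stack.mask()
    names = feature_names or stack.names
    X = np.column_stack([stack.layers[n][m] for n in names])
    vals = np.full(stack.grid.shape, np.nan)
    vals[m] = model.predict(X)
    return Raster(grid=stack.grid, values=vals)


def threshold_limited_map(suitability: Raster, threshold: float) -> Raster:
    """Binary map: 1 where suitability exceeds the threshold."""
    vals = np.where(np.isnan(suitability.values), np.nan,
                    (suitability.values >= threshold).astype(float))
    return Raster(grid=suitability.grid, values=vals)


@dataclass
class ConsensusMap:
    optimistic: Raster
    pessimistic: Raster
    n_scenarios: int


def consensus(maps: list[Raster]) -> ConsensusMap:
    """Optimistic (suitable in >= 1 scenario) and pessimistic (suitable in
    at least half, i.e. >= ceil(N/2)) consensus of binary maps."""
    if not maps:
        raise SdmError("need at least one binary map")
    grid = maps[0].grid
    stackv = np.stack([m.values for m in maps])
    count = np.nansum(stackv, axis=0)
    anynan = np.isnan(stackv).all(axis=0)
    n = len(maps)
    opt = np.where(anynan, np.nan, (count >= 1).astype(float))
    pes = np.where(anynan, np.nan, (count >= int(np.ceil(n / 2))).astype(float))
    return ConsensusMap(
        optimistic=Raster(grid, opt),
        pessimistic=Raster(grid, pes),
        n_scenarios=n,
    )
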