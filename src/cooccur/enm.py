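"""Presence-only ellipsoidal niche models and their geographic projections.

The niche envelope is a minimum-volume ellipsoid (MVE) in environment space
covering a fraction ``tau`` of the (deduplicated) training points; squared
Mahalanobis distance to the ellipsoid centre gives a continuous suitability
surface and, thresholded at the fitted radius, a binary species distribution
model (SDM).  SDMs come in two modes: *neutral* (clipped to the full study
domain) and *constrained* (clipped to the biogeographic slope(s) where the
species' occurrence points actually fall).

The estimator follows the scikit-learn API: ``EllipsoidNicheModel(tau=0.75)``
with ``fit(X)``, ``predict(X)`` (binary inclusion), ``score_samples(X)``
(continuous suitability) and fitted attributes ``center_``, ``shape_``,
``cutoff_``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from shapely.geometry.base import BaseGeometry
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .grid import BYTE_NODATA, FLOAT_NODATA, EnvStack, Raster
from .regions import RegionSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# exact minimum-volume enclosing ellipsoid
# ---------------------------------------------------------------------------

def khachiyan_ellipsoid(
    points: np.ndarray, tol: float = 1e-6, max_iter: int = 50000
) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-volume enclosing ellipsoid (Khachiyan/Todd-Yildirim iteration).

    Returns ``(center, A)`` such that ``(x - center)^T A (x - center) <= 1``
    for every input point (up to ``tol``).  Uses Frank-Wolfe steps on the
    D-optimal-design dual with away steps and rank-one inverse updates, which
    converges far faster than the plain Khachiyan update at tight tolerances.
    Stops when all dual gradients lie within ``(1 +- tol)(d+1)``.
    """
    P = np.asarray(points, dtype=float)
    n, d = P.shape
    if n < d + 1:
        raise ValueError("need at least d+1 points for an enclosing ellipsoid")
    Q = np.column_stack([P, np.ones(n)])  # lifted points, (n, d+1)
    dd = d + 1
    u = np.full(n, 1.0 / n)
    V = Q.T @ (u[:, None] * Q)
    Vinv = np.linalg.inv(V)
    for _ in range(max_iter):
        M = np.einsum("ij,ij->i", Q @ Vinv, Q)
        j = int(np.argmax(M))
        on = u > 0
        k_candidates = np.where(on)[0]
        k = int(k_candidates[np.argmin(M[k_candidates])])
        add_gap = M[j] / dd - 1.0
        away_gap = 1.0 - M[k] / dd
        if add_gap <= tol and away_gap <= tol:
            break
        if add_gap >= away_gap:
            t, lam = j, (M[j] - dd) / (dd * (M[j] - 1.0))
        else:
            t = k
            if u[k] >= 1.0 - 1e-12:  # all mass on one point: degenerate input
                raise np.linalg.LinAlgError("degenerate point configuration")
            lam = (M[k] - dd) / (dd * (M[k] - 1.0))  # negative
            lam = max(lam, -u[k] / (1.0 - u[k]))
        u *= 1.0 - lam
        u[t] += lam
        # Sherman-Morrison update of Vinv for V <- (1-lam) V + lam q q^T
        Vinv /= 1.0 - lam
        q = Q[t]
        w = Vinv @ q
        Vinv -= (lam / (1.0 + lam * (q @ w))) * np.outer(w, w)
    center = P.T @ u
    cov = P.T @ (u[:, None] * P) - np.outer(center, center)
    A = np.linalg.inv(cov) / d
    return center, A


def _reduce_to_hull(P: np.ndarray) -> np.ndarray:
    """The enclosing ellipsoid depends only on the convex hull (cheap for 2-D)."""
    if P.shape[1] == 2 and len(P) > 4:
        from scipy.spatial import QhullError, ConvexHull

        try:
            return P[ConvexHull(P).vertices]
        except QhullError:
            return P
    return P


def mve_params(
    points: np.ndarray, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray, float, str]:
    """Exact MVE of a point set as ``(mu, Sigma, c, method)``.

    ``Sigma`` and ``c`` define inclusion via squared Mahalanobis distance
    ``(x-mu)^T Sigma^{-1} (x-mu) <= c``; ``c`` is scaled so every input point
    is inside.  Uses Khachiyan when ``n >= 2 d``; the moment ellipsoid (mean,
    covariance, max Mahalanobis radius) otherwise, where the Khachiyan
    solution is poorly determined.
    """
    P = np.asarray(points, dtype=float)
    n, d = P.shape
    if n >= 2 * d:
        center, A = khachiyan_ellipsoid(_reduce_to_hull(P), tol=tol)
        sigma = np.linalg.inv(A)
        method = "khachiyan"
    else:
        center = P.mean(axis=0)
        sigma = np.cov(P.T, bias=False)
        if d == 1:
            sigma = np.atleast_2d(sigma)
        method = "moment"
    m2 = _mahalanobis_sq(P, center, sigma)
    c = float(m2.max()) * (1.0 + 1e-12) + 1e-12
    return center, sigma, c, method


def _mahalanobis_sq(X: np.ndarray, center: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    d = X - center
    try:
        sol = np.linalg.solve(sigma, d.T)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular shape matrix: {exc}") from exc
    return np.einsum("ij,ji->i", d, sol)


def ellipsoid_log_volume(sigma: np.ndarray, c: float) -> float:
    """log-volume of ``{m^2 <= c}`` up to the dimension-only unit-ball constant."""
    d = sigma.shape[0]
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    return 0.5 * (d * np.log(c) + logdet)


def _convex_layers(P: np.ndarray, n_layers: int = 3) -> np.ndarray:
    """Indices of the points on the first ``n_layers`` convex onion layers."""
    from scipy.spatial import QhullError, ConvexHull

    idx = np.arange(len(P))
    out: list[int] = []
    for _ in range(n_layers):
        if len(idx) <= P.shape[1] + 1:
            out.extend(int(i) for i in idx)
            break
        try:
            hull = ConvexHull(P[idx]).vertices
        except QhullError:
            out.extend(int(i) for i in idx)
            break
        out.extend(int(i) for i in idx[hull])
        idx = np.delete(idx, hull)
    return np.array(sorted(out), dtype=int)


def _cached_logvol(
    X: np.ndarray, idx, cache: dict[frozenset, float], tol: float
) -> float:
    """Exact-MVE log-volume of a subset, memoized by its hull vertex set."""
    key = frozenset(int(i) for i in idx)
    sub = sorted(key)
    if X.shape[1] == 2 and len(sub) > 4:
        from scipy.spatial import QhullError, ConvexHull

        try:
            key = frozenset(np.asarray(sub)[ConvexHull(X[sub]).vertices])
            sub = sorted(key)
        except QhullError:
            pass
    v = cache.get(key)
    if v is None:
        _, sigma, c, _ = mve_params(X[sub], tol=tol)
        v = ellipsoid_log_volume(sigma, c)
        cache[key] = v
    return v


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class EllipsoidNicheModel(BaseEstimator):
    """Minimum-volume ellipsoid niche envelope with partial data inclusion.

    Parameters
    ----------
    tau : float, default 0.75
        Data inclusion proportion in (0.5, 1]: the ellipsoid must cover at
        least ``ceil(tau * n)`` of the deduplicated training points.  Values
        below 1 discard environmental outliers (vagrants, misidentifications).
    max_trim_rounds : int, default 20
        Iterations of the trimming loop (fit, drop the ``floor((1-tau)*n)``
        points with largest Mahalanobis distance, refit) run to a fixed point.
    swap_refine_max_n : int, default 30
        For training sets up to this size, follow trimming with a
        deterministic single-swap local search (exchange one kept point for
        one dropped point whenever that shrinks the ellipsoid volume).
    tol : float, default 1e-6
        Khachiyan convergence tolerance.

    Attributes
    ----------
    center_ : (d,) ndarray — ellipsoid centre mu.
    shape_ : (d, d) ndarray — symmetric positive-definite shape matrix Sigma.
    cutoff_ : float — squared-Mahalanobis radius c of the fitted ellipsoid.
    support_ : (n_unique,) bool ndarray — points chosen for the final fit.
    n_train_ : int — number of deduplicated training points.
    method_ : str — "khachiyan" or "moment" (which exact-MVE form was used).
    """

    def __init__(
        self,
        tau: float = 0.75,
        max_trim_rounds: int = 20,
        swap_refine_max_n: int = 30,
        tol: float = 1e-6,
    ):
        self.tau = tau
        self.max_trim_rounds = max_trim_rounds
        self.swap_refine_max_n = swap_refine_max_n
        self.tol = tol

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y=None):
        if not (0.5 < self.tau <= 1.0):
            raise ValueError("tau must be in (0.5, 1]")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_points, n_layers)")
        Xu = np.unique(X, axis=0)
        n, d = Xu.shape
        if n < d + 1:
            raise ValueError(
                f"insufficient records for MVE: {n} unique points for {d} layers"
            )
        sds = Xu.std(axis=0)
        if np.any(sds == 0):
            degenerate = list(np.nonzero(sds == 0)[0])
            raise ValueError(f"degenerate (constant) layers at indices {degenerate}")
        cov = np.cov(Xu.T)
        if np.linalg.cond(cov) > 1e12:
            raise ValueError(
                "singular training covariance: some layers are collinear over "
                "the occurrence cells"
            )

        n_keep = int(np.ceil(self.tau * n))
        keep = self._select_subset(Xu, n_keep)
        center, sigma, c, method = mve_params(Xu[keep], tol=self.tol)

        self.center_ = center
        self.shape_ = sigma
        self.cutoff_ = c
        self.tau_ = self.tau
        self.n_train_ = n
        self.n_features_in_ = d
        self.support_ = np.zeros(n, dtype=bool)
        self.support_[keep] = True
        self.method_ = method
        # coverage invariant: the kept subset lies inside by construction
        covered = int(np.sum(self.mahalanobis_sq(Xu) <= self.cutoff_))
        if covered < n_keep:  # pragma: no cover - defensive
            raise RuntimeError("fitted ellipsoid lost coverage of its subset")
        return self

    def _select_subset(self, X: np.ndarray, n_keep: int) -> np.ndarray:
        """Indices of the subset whose exact MVE is (approximately) smallest."""
        n = len(X)
        keep = np.arange(n)
        if n_keep >= n:
            return keep
        # Iterative trimming to a fixed point.  Which points get trimmed is
        # insensitive to the ellipsoid tolerance, so the search rounds run at
        # a loose tolerance; only the final fit (in ``fit``) is tight.
        search_tol = max(self.tol, 1e-4)
        for _ in range(self.max_trim_rounds):
            center, sigma, c, _ = mve_params(X[keep], tol=search_tol)
            m2 = _mahalanobis_sq(X, center, sigma)
            new_keep = np.sort(np.argsort(m2, kind="stable")[:n_keep])
            if np.array_equal(new_keep, keep):
                break
            keep = new_keep
        if n <= self.swap_refine_max_n:
            cache: dict[frozenset, float] = {}
            if X.shape[1] == 2:
                keep = self._enumerate_outer_drops(X, keep, n_keep, cache)
            keep = self._swap_refine(X, keep, cache)
        return keep

    def _enumerate_outer_drops(
        self, X: np.ndarray, keep: np.ndarray, n_keep: int,
        cache: dict[frozenset, float],
    ) -> np.ndarray:
        """Enumerate drop sets among the outer convex layers (2-D only).

        Every point that shrinks the enclosing ellipsoid when dropped lies on
        an outer onion layer of the cloud, so enumerating drops from the
        first few layers (plus whatever trimming already dropped) is close to
        exhaustive at a fraction of the cost.
        """
        from itertools import combinations
        from math import comb

        n = len(X)
        n_drop = n - n_keep
        candidates = sorted(
            set(_convex_layers(X, 3)) | (set(range(n)) - set(int(i) for i in keep))
        )
        if n_drop < 1 or comb(len(candidates), n_drop) > 20000:
            return keep
        best_keep, best_vol = keep, _cached_logvol(X, keep, cache, self.tol)
        all_idx = set(range(n))
        for drops in combinations(candidates, n_drop):
            cand = np.fromiter(all_idx - set(drops), dtype=int)
            v = _cached_logvol(X, cand, cache, self.tol)
            if v < best_vol - 1e-12:
                best_keep, best_vol = cand, v
        return np.sort(best_keep)

    def _swap_refine(
        self, X: np.ndarray, keep: np.ndarray,
        cache: dict[frozenset, float] | None = None,
    ) -> np.ndarray:
        """Steepest-descent 1- and 2-point exchanges on ellipsoid log-volume.

        Single-point exchanges run to a local optimum; when they stall, the
        search tries exchanging pairs (which resolves the common case where
        two borderline points must move together), then resumes single
        exchanges.  Deterministic: steepest improving move wins.
        """
        from itertools import combinations

        if cache is None:
            cache = {}

        def logvol(idx) -> float:
            return _cached_logvol(X, idx, cache, self.tol)

        keep = set(int(i) for i in keep)
        dropped = set(range(len(X))) - keep
        best = logvol(keep)
        for _ in range(200):
            move, move_vol = None, best - 1e-10
            for i in keep:
                for j in dropped:
                    v = logvol(keep - {i} | {j})
                    if v < move_vol:
                        move, move_vol = ({i}, {j}), v
            if move is None and len(dropped) >= 2:
                for ii in combinations(sorted(keep), 2):
                    for jj in combinations(sorted(dropped), 2):
                        v = logvol(keep - set(ii) | set(jj))
                        if v < move_vol:
                            move, move_vol = (set(ii), set(jj)), v
            if move is None:
                break
            out_pts, in_pts = move
            keep = keep - out_pts | in_pts
            dropped = dropped - in_pts | out_pts
            best = move_vol
        return np.sort(np.fromiter(keep, dtype=int))

    # -- inference ---------------------------------------------------------

    def mahalanobis_sq(self, X) -> np.ndarray:
        check_is_fitted(self, "center_")
        return _mahalanobis_sq(np.asarray(X, dtype=float), self.center_, self.shape_)

    def predict(self, X) -> np.ndarray:
        """Binary inclusion: 1 inside the fitted ellipsoid, 0 outside."""
        return (self.mahalanobis_sq(X) <= self.cutoff_).astype(int)

    def score_samples(self, X) -> np.ndarray:
        """Unnormalized continuous suitability ``exp(-m^2 / 2)``."""
        return np.exp(-0.5 * self.mahalanobis_sq(X))

    @property
    def log_volume_(self) -> float:
        check_is_fitted(self, "center_")
        return ellipsoid_log_volume(self.shape_, self.cutoff_)


def fit_mve(values: np.ndarray, tau: float = 0.75, **kwargs) -> EllipsoidNicheModel:
    """Fit an :class:`EllipsoidNicheModel` to an environment-value matrix."""
    return EllipsoidNicheModel(tau=tau, **kwargs).fit(values)


# ---------------------------------------------------------------------------
# raster projection
# ---------------------------------------------------------------------------

def extract_env_values(
    points: pd.DataFrame, stack: EnvStack, species: str | None = None
) -> np.ndarray:
    """Environment values at the cells containing each point.

    Points outside the extent or on NODATA cells are dropped with a logged
    count; raises if nothing remains.
    """
    i, j = stack.grid.cell_index(points["x"].to_numpy(), points["y"].to_numpy())
    inside = i >= 0
    valid = np.zeros(len(points), dtype=bool)
    vm = stack.valid_mask
    valid[inside] = vm[j[inside], i[inside]]
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info(
            "extract_env_values dropped %d/%d points (outside extent or NODATA)",
            n_dropped, len(points),
        )
    if not valid.any():
        who = species or (points["species"].iloc[0] if len(points) else "<empty>")
        raise ValueError(f"all occurrence points of {who} fall on NODATA or outside")
    return stack.values_at_cells(i[valid], j[valid])


def _check_layers(model: EllipsoidNicheModel, stack: EnvStack) -> None:
    check_is_fitted(model, "center_")
    if model.n_features_in_ != stack.n_layers:
        raise ValueError(
            f"model fitted on {model.n_features_in_} layers, stack has "
            f"{stack.n_layers} ({stack.names})"
        )


def suitability_surface(
    model: EllipsoidNicheModel, stack: EnvStack, meta: dict | None = None
) -> Raster:
    """Continuous suitability ``exp(-m^2/2)``, rescaled to max 1 over valid cells."""
    _check_layers(model, stack)
    E, ji = stack.env_matrix()
    out = np.full(stack.grid.shape, FLOAT_NODATA, dtype=np.float32)
    if len(E):
        s = model.score_samples(E)
        peak = s.max()
        if peak > 0:
            s = s / peak
        out[ji[:, 0], ji[:, 1]] = s
    return Raster(out, stack.grid, nodata=FLOAT_NODATA, meta=dict(meta or {}))


def binarize_sdm(
    model: EllipsoidNicheModel, stack: EnvStack, meta: dict | None = None
) -> Raster:
    """Binary SDM: 1 where the cell environment falls inside the ellipsoid."""
    _check_layers(model, stack)
    E, ji = stack.env_matrix()
    out = np.full(stack.grid.shape, BYTE_NODATA, dtype=np.uint8)
    if len(E):
        out[ji[:, 0], ji[:, 1]] = (
            model.mahalanobis_sq(E) <= model.cutoff_
        ).astype(np.uint8)
    return Raster(out, stack.grid, nodata=BYTE_NODATA, meta=dict(meta or {}))


def clip_to_region(raster: Raster, region: BaseGeometry, mode: str = "neutral") -> Raster:
    """NODATA-out cells whose centroids fall outside ``region``.

    ``mode`` is recorded in provenance only; callers pass the full study
    polygon for neutral models and the species' slope polygon(s) for
    constrained ones.
    """
    import shapely

    X, Y = raster.grid.centroids()
    pts = shapely.points(X.ravel(), Y.ravel())
    inside = shapely.covers(region, pts).reshape(raster.grid.shape)
    if not (inside & raster.valid_mask).any():
        raise ValueError("region does not intersect any valid raster cell")
    out = raster.copy()
    out.values = out.values.copy()
    out.values[~inside] = raster.nodata
    out.meta["mode"] = mode
    return out


def constrained_region(regions: RegionSet, points: pd.DataFrame) -> BaseGeometry:
    """Union of the slope polygons containing at least one occurrence point.

    Mirrors the post-hoc accessible-area assignment: overlay the species'
    cleaned points on the slopes and keep every slope that holds any of them.
    """
    from shapely.ops import unary_union

    slopes = regions.slope_of_points(points["x"].to_numpy(), points["y"].to_numpy())
    if not slopes:
        raise ValueError("occurrence points fall on no biogeographic slope")
    return unary_union([regions[s] for s in slopes])
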