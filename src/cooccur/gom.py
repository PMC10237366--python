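"""Grade-of-membership decomposition of site x species presence matrices.

Each site (hexagon) is modelled as a mixture of K "motifs" — probability
vectors over species representing recurring geographic communities — under
the multinomial likelihood

    l = sum_n sum_s x_ns log( sum_k omega_nk theta_ks )

with omega (sites x K) and theta (K x species) rows on the simplex.  This is
the admixture model family used for population-genetic STRUCTURE-style
analyses, applied to presence-absence data; fitting is plain EM with seeded
random restarts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

_FLOOR = 1e-12  # numerical floor on mixture probabilities inside logs


def gom_loglik(omega: np.ndarray, theta: np.ndarray, X: np.ndarray) -> float:
    """Multinomial grade-of-membership log-likelihood.

    Validates the simplex constraints (tolerance 1e-6); returns ``-inf``
    when some present entry has zero mixture probability.
    """
    omega = np.asarray(omega, float)
    theta = np.asarray(theta, float)
    X = np.asarray(X, float)
    if omega.shape[0] != X.shape[0] or theta.shape[1] != X.shape[1] \
            or omega.shape[1] != theta.shape[0]:
        raise ValueError("dimension mismatch between omega, theta, X")
    for M, name in ((omega, "omega"), (theta, "theta")):
        if (M < -1e-6).any() or np.abs(M.sum(axis=1) - 1).max() > 1e-6:
            raise ValueError(f"{name} rows violate the simplex constraint")
    P = omega @ theta
    present = X > 0
    if not present.any():
        return 0.0
    if (P[present] <= 0).any():
        return -np.inf
    return float((X[present] * np.log(P[present])).sum())


class GradeOfMembership(BaseEstimator, TransformerMixin):
    """EM-fitted multinomial grade-of-membership (admixture) model.

    Parameters
    ----------
    n_motifs : int — number of motifs K (>= 1).
    tol : float, default 0.1
        Convergence tolerance on the log-likelihood change per iteration.
    max_iter : int, default 500
    n_starts : int, default 10
        Seeded random restarts; the best final log-likelihood wins.
    random_state : int, default 0

    Attributes
    ----------
    omega_ : (n_sites, K) ndarray — site memberships (rows on the simplex).
    theta_ : (K, n_species) ndarray — motif compositions (rows on the simplex).
    loglik_trace_ : list[float] — per-iteration log-likelihood of the best
        start (non-decreasing, an EM guarantee).
    site_mask_ : bool ndarray — sites kept (empty sites are dropped).
    """

    def __init__(
        self,
        n_motifs: int = 2,
        tol: float = 0.1,
        max_iter: int = 500,
        n_starts: int = 10,
        random_state: int = 0,
    ):
        self.n_motifs = n_motifs
        self.tol = tol
        self.max_iter = max_iter
        self.n_starts = n_starts
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (sites x species)")
        if self.n_motifs < 1:
            raise ValueError("n_motifs must be >= 1")
        if self.n_motifs > X.shape[1]:
            raise ValueError("n_motifs exceeds the species count")
        site_mask = X.sum(axis=1) > 0
        n_empty = int((~site_mask).sum())
        if n_empty:
            logger.info("dropping %d empty sites before the GoM fit", n_empty)
        Xf = X[site_mask]

        best = None
        for start in range(self.n_starts):
            rng = np.random.default_rng([self.random_state, start])
            omega, theta, trace = _em_run(
                Xf, self.n_motifs, rng, self.tol, self.max_iter
            )
            if best is None or trace[-1] > best[2][-1]:
                best = (omega, theta, trace, start)
        self.omega_, self.theta_, self.loglik_trace_, self.best_start_ = best
        self.site_mask_ = site_mask
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X=None) -> np.ndarray:
        """Site membership matrix omega of the fitted sites."""
        check_is_fitted(self, "omega_")
        return self.omega_

    def fit_transform(self, X, y=None, **kwargs) -> np.ndarray:
        return self.fit(X).transform(X)

    @property
    def loglik_(self) -> float:
        check_is_fitted(self, "loglik_trace_")
        return self.loglik_trace_[-1]


def _em_run(
    X: np.ndarray, K: int, rng, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """One EM run from a Dirichlet(1) random start."""
    n, s = X.shape
    omega = rng.dirichlet(np.ones(K), size=n)
    theta = rng.dirichlet(np.ones(s), size=K)
    row_tot = X.sum(axis=1, keepdims=True)
    trace: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        P = np.maximum(omega @ theta, _FLOOR)
        R = X / P
        omega_new = omega * (R @ theta.T) / row_tot
        theta_new = theta * (omega.T @ R)
        theta_new /= theta_new.sum(axis=1, keepdims=True)
        omega, theta = omega_new, theta_new
        ll = float(
            (X[X > 0] * np.log(np.maximum(omega @ theta, _FLOOR)[X > 0])).sum()
        )
        trace.append(ll)
        if abs(ll - prev) < tol:
            break
        prev = ll
    return omega, theta, trace


def fit_gom(
    pam_sites: np.ndarray,
    K: int,
    tol: float = 0.1,
    max_iter: int = 500,
    n_starts: int = 10,
    seed: int = 0,
) -> GradeOfMembership:
    """Fit a :class:`GradeOfMembership` model to a sites x species matrix."""
    return GradeOfMembership(
        n_motifs=K, tol=tol, max_iter=max_iter, n_starts=n_starts, random_state=seed
    ).fit(pam_sites)


def match_motifs(theta: np.ndarray, theta_ref: np.ndarray) -> np.ndarray:
    """Optimal motif label permutation (Hungarian assignment on correlation).

    Returns the permutation ``perm`` such that ``theta[perm]`` best matches
    ``theta_ref`` row-by-row.
    """
    from scipy.optimize import linear_sum_assignment

    K = theta.shape[0]
    C = np.zeros((K, K))
    for a in range(K):
        for b in range(K):
            C[a, b] = -np.corrcoef(theta[a], theta_ref[b])[0, 1]
    rows, cols = linear_sum_assignment(C)
    perm = np.empty(K, dtype=int)
    perm[cols] = rows
    return perm


def motif_series(
    pam_sites: np.ndarray,
    k_range=range(2, 15),
    tol: float = 0.1,
    n_starts: int = 10,
    seed: int = 0,
) -> dict[int, GradeOfMembership]:
    """Fit one GoM model per K; logs the best start per K.

    The per-site dominant motif for each K is ``omega_.argmax(axis=1)``.
    """
    fits = {}
    for K in k_range:
        fit = fit_gom(pam_sites, K, tol=tol, n_starts=n_starts, seed=seed)
        logger.info("GoM K=%d: loglik %.3f (best start %d)", K, fit.loglik_, fit.best_start_)
        fits[K] = fit
    return fits


def motif_map(fit: GradeOfMembership, hex_ids: list[str]) -> pd.DataFrame:
    """Per-site omega rows and dominant motif, joined to hexagon ids."""
    kept = [h for h, m in zip(hex_ids, fit.site_mask_) if m]
    df = pd.DataFrame(
        fit.omega_, index=kept,
        columns=[f"motif_{k}" for k in range(fit.omega_.shape[1])],
    )
    df.insert(0, "dominant_motif", fit.omega_.argmax(axis=1))
    df.index.name = "hex_id"
    return df.reset_index()
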