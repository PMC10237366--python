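"""Species clustering on hexagon-occupancy vectors and cross-season stability.

Species are clustered by k-means on their binary hexagon-occupancy rows, with
the number of clusters selected by the gap statistic (uniform reference over
the observed feature ranges, first-SE-max rule).  June and December cluster
solutions are then cross-compared: each June cluster's best-match overlap
fraction with any December cluster classifies it as *stable* (> 2/3 of its
resident species co-occur in one December cluster), *split* (1/3 to 2/3) or
*diffuse* (at most 1/3); clusters with fewer than 5 resident species are
*unknown*.  A UPGMA dendrogram is provided for visualization only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .hexgrid import PAM

STABLE_BAND = 2.0 / 3.0  # ">66%" read as rounded two-thirds
DIFFUSE_BAND = 1.0 / 3.0


# ---------------------------------------------------------------------------
# gap statistic
# ---------------------------------------------------------------------------

def _dispersion(X: np.ndarray, k: int, n_init: int, seed: int) -> float:
    """Pooled within-cluster dispersion W_k of the best k-means partition.

    W_k = sum_r D_r / (2 n_r) with D_r the sum of pairwise Euclidean
    distances inside cluster r — the distance-based (unsquared) form used by
    the standard gap-statistic tooling, which is better behaved than raw
    inertia on binary occupancy data.
    """
    from scipy.spatial.distance import pdist

    if k == 1:
        labels = np.zeros(len(X), dtype=int)
    else:
        labels = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X).labels_
    w = 0.0
    for r in range(k):
        sub = X[labels == r]
        if len(sub) > 1:
            w += pdist(sub).sum() / len(sub)
    return float(w)


def gap_statistic(
    X: np.ndarray | PAM,
    k_max: int,
    B: int = 50,
    seed: int = 0,
    n_init: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Gap-statistic selection of the k-means cluster count.

    Gap(k) = mean_b log(W*_kb) - log(W_k) with B reference sets drawn
    uniformly over each feature's observed range.  The optimum is the
    smallest k with Gap(k) >= Gap(k+1) - SE(k+1) (first-SE-max rule, the
    default of the standard gap-statistic tooling); falls back to ``k_max``
    when no k satisfies it.  Returns (optimal k, curve with columns k, log_w,
    gap, se).
    """
    if isinstance(X, PAM):
        X = X.matrix.astype(float)
    X = np.asarray(X, dtype=float)
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    ks = np.arange(1, k_max + 1)

    log_w = np.array(
        [np.log(_dispersion(X, k, n_init, seed)) for k in ks]
    )
    ref_log_w = np.empty((B, len(ks)))
    for b in range(B):
        Xb = rng.uniform(lo, hi, size=X.shape)
        ref_seed = int(rng.integers(2**31 - 1))
        ref_log_w[b] = [np.log(_dispersion(Xb, k, n_init, ref_seed)) for k in ks]
    gap = ref_log_w.mean(axis=0) - log_w
    se = ref_log_w.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)

    optimal = int(ks[-1])
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - se[i + 1]:
            optimal = int(ks[i])
            break
    curve = pd.DataFrame({"k": ks, "log_w": log_w, "gap": gap, "se": se})
    return optimal, curve


class GapKMeans(BaseEstimator, ClusterMixin):
    """K-means with the cluster count chosen by the gap statistic.

    Parameters mirror :func:`gap_statistic` plus the final-fit restart count.

    Attributes
    ----------
    n_clusters_ : int — selected cluster count (floored at ``min_k``).
    gap_k_ : int — raw gap-statistic optimum (may be 1).
    labels_ : (n,) int ndarray — 0-based cluster labels from the final fit.
    inertia_ : float — within-cluster sum of squares of the final fit.
    gap_curve_ : DataFrame — full gap curve with standard errors.
    """

    def __init__(
        self,
        k_max: int = 10,
        B: int = 50,
        n_init: int = 10,
        n_init_final: int = 25,
        min_k: int = 2,
        random_state: int = 0,
    ):
        self.k_max = k_max
        self.B = B
        self.n_init = n_init
        self.n_init_final = n_init_final
        self.min_k = min_k
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.gap_k_, self.gap_curve_ = gap_statistic(
            X, self.k_max, B=self.B, seed=self.random_state, n_init=self.n_init
        )
        self.n_clusters_ = max(self.gap_k_, self.min_k)
        km = KMeans(
            n_clusters=self.n_clusters_,
            n_init=self.n_init_final,
            random_state=self.random_state,
        ).fit(X)
        self.labels_ = km.labels_
        self.inertia_ = float(km.inertia_)
        self.cluster_centers_ = km.cluster_centers_
        return self


# ---------------------------------------------------------------------------
# species clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterSolution:
    """A k-means partition of species by hexagon occupancy."""

    season: str
    mode: str
    K: int
    labels: dict[str, int]  # species -> cluster id in 1..K
    inertia: float
    seed: int
    gap_curve: pd.DataFrame | None = field(default=None, repr=False)

    def members(self, cluster: int) -> set[str]:
        return {s for s, c in self.labels.items() if c == cluster}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": list(self.labels),
                "season": self.season,
                "mode": self.mode,
                "cluster": list(self.labels.values()),
            }
        )


def kmeans_species(
    pam: PAM, K: int, seed: int = 0, n_init: int = 25,
    gap_curve: pd.DataFrame | None = None,
) -> ClusterSolution:
    """Cluster PAM rows (species occupancy vectors) into K groups."""
    X = pam.matrix.astype(float)
    n_distinct = len(np.unique(X, axis=0))
    if K > n_distinct:
        raise ValueError(
            f"K={K} exceeds the {n_distinct} distinct occupancy vectors"
        )
    km = KMeans(n_clusters=K, n_init=n_init, random_state=seed).fit(X)
    labels = {sp: int(lbl) + 1 for sp, lbl in zip(pam.species, km.labels_)}
    return ClusterSolution(
        pam.season, pam.mode, K, labels, float(km.inertia_), seed, gap_curve
    )


def cluster_species(
    pam: PAM, k_max: int = 10, B: int = 50, seed: int = 0, n_init: int = 25
) -> ClusterSolution:
    """Gap-statistic K selection followed by the final k-means fit."""
    optimal, curve = gap_statistic(pam, k_max, B=B, seed=seed)
    return kmeans_species(pam, max(optimal, 2), seed=seed, n_init=n_init,
                          gap_curve=curve)


# ---------------------------------------------------------------------------
# UPGMA visualization tree
# ---------------------------------------------------------------------------

def upgma_tree(pam: PAM, metric: str = "euclidean") -> tuple[np.ndarray, str]:
    """UPGMA (average-linkage) dendrogram of species occupancy vectors.

    Returns the scipy linkage matrix and a Newick string.  Visualization
    only; no downstream analysis consumes the tree.
    """
    if metric not in ("euclidean", "jaccard"):
        raise ValueError("metric must be 'euclidean' or 'jaccard'")
    if len(pam.species) < 2:
        raise ValueError("need at least 2 species")
    X = pam.matrix.astype(bool) if metric == "jaccard" else pam.matrix.astype(float)
    Z = linkage(pdist(X, metric=metric), method="average")
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(Z, pam.species)
    return Z, str(tree).strip()


# ---------------------------------------------------------------------------
# cross-season stability
# ---------------------------------------------------------------------------

def cross_season_overlap(
    source: ClusterSolution,
    target: ClusterSolution,
    shared_species: list[str],
    direction: str | None = None,
) -> pd.DataFrame:
    """Best-match overlap of each source cluster with the target partition.

    Restricted to ``shared_species`` (year-round residents).  For a source
    cluster c, f(c) = max_d |c n d| / |c| over target clusters d.  Clusters
    with no shared species get NaN overlap and are excluded from banding.
    """
    shared = [s for s in shared_species if s in source.labels and s in target.labels]
    if not shared:
        raise ValueError("no shared species between the two solutions")
    direction = direction or f"{source.season}->{target.season}"
    rows = []
    for c in range(1, source.K + 1):
        members = [s for s in shared if source.labels[s] == c]
        if not members:
            rows.append((c, 0, None, np.nan))
            continue
        counts = pd.Series([target.labels[s] for s in members]).value_counts()
        rows.append((c, len(members), int(counts.index[0]), counts.iloc[0] / len(members)))
    out = pd.DataFrame(rows, columns=["cluster", "size", "best_match", "overlap"])
    out["direction"] = direction
    return out


def classify_stability(overlaps: pd.DataFrame, min_size: int = 5) -> pd.DataFrame:
    """Attach stability categories to an overlap table.

    stable: f > 2/3; split: 1/3 < f <= 2/3; diffuse: f <= 1/3; unknown:
    fewer than ``min_size`` shared species (band thresholds are exact thirds,
    the 66%/33% figures being rounded thirds).
    """
    def band(row) -> str:
        if np.isnan(row["overlap"]):
            return "empty"
        if row["size"] < min_size:
            return "unknown"
        f = row["overlap"]
        if f > STABLE_BAND:
            return "stable"
        if f > DIFFUSE_BAND:
            return "split"
        return "diffuse"

    out = overlaps.copy()
    out["category"] = out.apply(band, axis=1)
    return out


def species_categories(
    solution: ClusterSolution, report: pd.DataFrame
) -> dict[str, str]:
    """Map each species to the stability category of its cluster."""
    cat = dict(zip(report["cluster"], report["category"]))
    return {sp: cat.get(c, "none") for sp, c in solution.labels.items()}
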