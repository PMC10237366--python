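"""Schoener's D niche similarity, randomization nulls and group comparisons.

Schoener's D between two continuous suitability surfaces normalized to
probability distributions p, q over the shared valid cells:

    D = 1 - (1/2) * sum_i |p_i - q_i|

D = 1 for identical surfaces, 0 for disjoint supports.  Observed per-species
June-vs-December D values are compared against a null built from random
cross-season species pairings, across cluster-stability categories (Wilcoxon
rank-sum), against seasonal effort differences (Spearman), and between the
migrant-related species subset and random same-size subsets (Fisher's exact
test on category counts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import lgamma

import numpy as np
import pandas as pd
from scipy import stats

from .grid import Raster

logger = logging.getLogger(__name__)

CATEGORIES = ["stable", "split", "diffuse", "unknown"]


# ---------------------------------------------------------------------------
# Schoener's D
# ---------------------------------------------------------------------------

def schoener_d(r1: Raster, r2: Raster) -> float:
    """Schoener's D of two suitability rasters on shared grid geometry.

    Each surface is normalized over its own valid (non-NODATA) cells and the
    sum runs over the union of both supports, so two surfaces clipped to
    disjoint accessible areas score D = 0 rather than being undefined.
    """
    if r1.values.shape != r2.values.shape:
        raise ValueError("rasters do not share geometry")

    def normalized(r: Raster) -> np.ndarray:
        v = np.where(r.valid_mask, np.asarray(r.values, dtype=float), 0.0)
        total = v.sum()
        if total <= 0:
            raise ValueError("surface with no positive suitability")
        return v / total

    p, q = normalized(r1), normalized(r2)
    return float(1.0 - 0.5 * np.abs(p - q).sum())


# ---------------------------------------------------------------------------
# observed table and randomized null
# ---------------------------------------------------------------------------

def overlap_table(
    june_surfaces: dict[str, Raster],
    december_surfaces: dict[str, Raster],
    categories: dict[str, str] | None = None,
    point_counts: dict[str, tuple[int, int]] | None = None,
    mode: str = "",
) -> pd.DataFrame:
    """Per-resident-species June-vs-December D with category and effort delta.

    Species present in only one season are excluded (with a log note);
    ``categories`` maps species to their June-cluster stability category and
    ``point_counts`` to (june, december) cleaned record counts.
    """
    resident = sorted(set(june_surfaces) & set(december_surfaces))
    skipped = sorted(set(june_surfaces) ^ set(december_surfaces))
    if skipped:
        logger.info("overlap_table: %d single-season species excluded", len(skipped))
    rows = []
    for sp in resident:
        d = schoener_d(june_surfaces[sp], december_surfaces[sp])
        nj, nd = (point_counts or {}).get(sp, (np.nan, np.nan))
        rows.append(
            {
                "species": sp,
                "D": d,
                "category": (categories or {}).get(sp, "none"),
                "delta_points": nj - nd if not np.isnan(nj) else np.nan,
                "mode": mode,
            }
        )
    return pd.DataFrame(rows, columns=["species", "D", "category", "delta_points", "mode"])


@dataclass
class NullDistribution:
    """Randomized cross-season pairings of niche models."""

    draws: np.ndarray
    seed: int
    pairs: list[tuple[str, str]] = field(default_factory=list, repr=False)

    @property
    def n_draws(self) -> int:
        return len(self.draws)


def randomized_null(
    june_surfaces: dict[str, Raster],
    december_surfaces: dict[str, Raster],
    n_draws: int = 1000,
    seed: int = 0,
) -> NullDistribution:
    """D for random June-species x December-species pairings (i != j).

    Destroys the within-species seasonal link while keeping the marginal
    model pools, so a species' own conservatism cannot leak into the null.
    """
    june_ids = sorted(june_surfaces)
    dec_ids = sorted(december_surfaces)
    if len(june_ids) < 2 or len(dec_ids) < 2:
        raise ValueError("need at least 2 species per season")
    rng = np.random.default_rng(seed)
    draws = np.empty(n_draws)
    pairs = []
    for b in range(n_draws):
        while True:
            i = june_ids[rng.integers(len(june_ids))]
            j = dec_ids[rng.integers(len(dec_ids))]
            if i != j:
                break
        draws[b] = schoener_d(june_surfaces[i], december_surfaces[j])
        pairs.append((i, j))
    return NullDistribution(draws, seed, pairs)


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def _mean_ci(x: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    m = float(x.mean())
    if len(x) < 2 or np.ptp(x) == 0:
        return m, 0.0
    half = stats.t.ppf(0.5 + level / 2, len(x) - 1) * stats.sem(x)
    return m, float(half)


def observed_vs_null_test(observed, null: NullDistribution | np.ndarray) -> dict:
    """Welch two-sample t of observed D values against the randomized null."""
    obs = np.asarray(observed, dtype=float)
    nul = null.draws if isinstance(null, NullDistribution) else np.asarray(null, float)
    if len(obs) == 0 or len(nul) == 0:
        raise ValueError("both samples must be non-empty")
    if np.ptp(obs) == 0 and np.ptp(nul) == 0:
        t, df, p = (0.0, float(len(obs) + len(nul) - 2),
                    1.0 if obs.mean() == nul.mean() else 0.0)
    else:
        res = stats.ttest_ind(obs, nul, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    mo, ho = _mean_ci(obs)
    mn, hn = _mean_ci(nul)
    return {
        "t": t, "df": df, "p": p,
        "mean_observed": mo, "ci95_observed": ho, "n_observed": len(obs),
        "mean_null": mn, "ci95_null": hn, "n_null": len(nul),
    }


def _rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum: exact for combined n <= 50, else normal
    approximation with continuity correction.  Returns (W, p) with W the
    rank-sum-derived Mann-Whitney statistic of the first sample."""
    method = "exact" if len(x) + len(y) <= 50 else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def category_comparisons(records: pd.DataFrame, min_n: int = 2) -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum of D between stability categories.

    Categories with fewer than ``min_n`` records are skipped (logged).
    Also reports each category's mean D with a 95% CI half-width.
    """
    groups = {}
    for cat in CATEGORIES:
        vals = records.loc[records["category"] == cat, "D"].to_numpy()
        if len(vals) >= min_n:
            groups[cat] = vals
        elif len(vals):
            logger.info("category %s has %d < %d records; skipped", cat, len(vals), min_n)
    if len(groups) < 2:
        raise ValueError("need at least 2 categories with enough records")
    rows = []
    names = [c for c in CATEGORIES if c in groups]
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            W, p = _rank_sum(groups[a], groups[b])
            ma, ha = _mean_ci(groups[a])
            mb, hb = _mean_ci(groups[b])
            rows.append(
                {
                    "category_a": a, "category_b": b, "W": W, "p": p,
                    "mean_a": ma, "ci95_a": ha, "n_a": len(groups[a]),
                    "mean_b": mb, "ci95_b": hb, "n_b": len(groups[b]),
                }
            )
    return pd.DataFrame(rows)


def effort_bias_check(records: pd.DataFrame) -> dict:
    """Spearman rank correlation of D against |June - December| record counts."""
    sub = records.dropna(subset=["delta_points"])
    if len(sub) < 3:
        raise ValueError("need at least 3 records with effort deltas")
    d = sub["D"].to_numpy()
    delta = np.abs(sub["delta_points"].to_numpy())
    if np.ptp(d) == 0 or np.ptp(delta) == 0:
        return {"rho": np.nan, "p": np.nan, "n": len(sub),
                "note": "constant input; correlation undefined"}
    rho, p = stats.spearmanr(d, delta)
    return {"rho": float(rho), "p": float(p), "n": len(sub)}


# ---------------------------------------------------------------------------
# Fisher's exact test (2 x C) and the migrant-subset comparison
# ---------------------------------------------------------------------------

def fisher_exact_2xc(table: np.ndarray) -> float:
    """Two-sided Fisher's exact test for a 2 x C contingency table.

    Conditional on both margins; the two-sided p sums the probabilities of
    all tables no more probable than the observed one (the same ordering rule
    R's ``fisher.test`` uses).  Exact enumeration over the first row; falls
    back to a chi-square approximation only for infeasibly large tables.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("table must be 2 x C")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    col = t.sum(axis=0)
    r1 = int(t[0].sum())
    N = int(t.sum())
    if N == 0:
        return 1.0

    def log_p(a: tuple[int, ...]) -> float:
        lp = -(lgamma(N + 1) - lgamma(r1 + 1) - lgamma(N - r1 + 1))
        for aj, cj in zip(a, col):
            lp += lgamma(cj + 1) - lgamma(aj + 1) - lgamma(cj - aj + 1)
        return lp

    n_tables = np.prod([c + 1 for c in col])
    if n_tables > 5e6:  # pragma: no cover - defensive for huge tables
        chi2 = stats.chi2_contingency(t)[1]
        logger.warning("table too large for exact enumeration; chi-square p used")
        return float(chi2)

    obs_lp = log_p(tuple(int(v) for v in t[0]))
    total = 0.0
    p_le = 0.0

    def rec(j: int, remaining: int, acc: list[int]):
        nonlocal total, p_le
        if j == len(col) - 1:
            if remaining <= col[j]:
                lp = log_p(tuple(acc + [remaining]))
                pr = np.exp(lp)
                total += pr
                if lp <= obs_lp + 1e-7:
                    p_le += pr
            return
        lo = max(0, remaining - int(col[j + 1:].sum()))
        hi = min(col[j], remaining)
        for a in range(lo, hi + 1):
            rec(j + 1, remaining - a, acc + [a])

    rec(0, r1, [])
    return float(min(p_le / total, 1.0))


def migrant_subsample_test(
    records: pd.DataFrame,
    migrant_related: list[str],
    n_subsamples: int = 500,
    seed: int = 0,
) -> dict:
    """Do migrant-related species distribute across stability categories
    differently from random same-size subsets?

    Tabulates category counts for the migrant-related set and for
    ``n_subsamples`` random subsets of the same size, then runs a Fisher
    exact test of the migrant counts against the rounded mean random counts
    (2 x C, zero-count columns dropped).
    """
    species = records["species"].tolist()
    mig = [s for s in migrant_related if s in set(species)]
    if len(mig) < 5:
        raise ValueError("migrant-related set must contain at least 5 scored species")
    cats = dict(zip(records["species"], records["category"]))

    def counts(subset) -> np.ndarray:
        c = pd.Series([cats[s] for s in subset]).value_counts()
        return np.array([int(c.get(k, 0)) for k in CATEGORIES])

    mig_counts = counts(mig)
    rng = np.random.default_rng(seed)
    rand = np.zeros((n_subsamples, len(CATEGORIES)), dtype=int)
    pool = np.array(species)
    for b in range(n_subsamples):
        rand[b] = counts(pool[rng.choice(len(pool), size=len(mig), replace=False)])
    expected = np.round(rand.mean(axis=0)).astype(int)

    keep = (mig_counts + expected) > 0
    table = np.vstack([mig_counts[keep], expected[keep]])
    p = fisher_exact_2xc(table) if table.shape[1] > 1 else 1.0
    return {
        "p": p,
        "categories": [c for c, k in zip(CATEGORIES, keep) if k],
        "migrant_counts": mig_counts[keep].tolist(),
        "expected_random_counts": expected[keep].tolist(),
        "n_migrant_related": len(mig),
        "n_subsamples": n_subsamples,
        "seed": seed,
    }
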