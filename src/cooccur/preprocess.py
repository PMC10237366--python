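"""Occurrence-table cleaning: monthly split, spatial thinning, minimum counts.

An occurrence table is a pandas DataFrame with columns ``species`` (str),
``x``/``y`` (projected km) and ``month`` (1-12).  Coordinates must be in a
projected system: thinning distances are Euclidean km.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OCC_COLUMNS = ["species", "x", "y", "month"]


def _check_table(occ: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in OCC_COLUMNS if c not in occ.columns]
    if missing:
        raise ValueError(f"occurrence table missing columns: {missing}")
    return occ


def split_by_month(
    occ: pd.DataFrame, months: set[int] = frozenset({6, 12})
) -> dict[int, pd.DataFrame]:
    """Partition rows by month, dropping (and counting) all other months."""
    if not months:
        raise ValueError("months must be non-empty")
    _check_table(occ)
    out = {
        m: occ[occ["month"] == m].reset_index(drop=True) for m in sorted(months)
    }
    n_dropped = len(occ) - sum(len(t) for t in out.values())
    if n_dropped:
        logger.info("split_by_month dropped %d rows outside %s", n_dropped, sorted(months))
    return out


def _thin_points(xy: np.ndarray, min_dist: float) -> np.ndarray:
    """Greedy scan in input order; returns a boolean keep mask.

    A point is kept iff it is >= ``min_dist`` from every already-kept point
    (removal is strictly-within: pairs at exactly ``min_dist`` both survive).
    """
    n = len(xy)
    keep = np.zeros(n, dtype=bool)
    kept = np.empty((n, 2))
    k = 0
    d2 = min_dist * min_dist
    for idx in range(n):
        p = xy[idx]
        if k == 0 or not (np.sum((kept[:k] - p) ** 2, axis=1) < d2).any():
            kept[k] = p
            k += 1
            keep[idx] = True
    return keep


def thin_spatial(occ: pd.DataFrame, min_dist_km: float = 1.0) -> pd.DataFrame:
    """Spatially thin each species independently (greedy, input-row order).

    Deterministic given row order: the first point of a too-close pair wins.
    """
    _check_table(occ)
    if occ.empty:
        return occ.reset_index(drop=True)
    keep = np.zeros(len(occ), dtype=bool)
    for _, idx in occ.groupby("species", sort=False).indices.items():
        xy = occ.iloc[idx][["x", "y"]].to_numpy(dtype=float)
        keep[idx] = _thin_points(xy, min_dist_km)
    return occ[keep].reset_index(drop=True)


def filter_min_records(
    occ: pd.DataFrame, n_min: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop species with fewer than ``n_min`` rows.

    Returns the filtered table and an exclusion table with columns
    ``species, n_records, reason``.  A species with exactly ``n_min`` rows is
    retained.
    """
    _check_table(occ)
    if occ.empty:
        return occ.reset_index(drop=True), pd.DataFrame(
            columns=["species", "n_records", "reason"]
        )
    counts = occ.groupby("species", sort=False).size()
    bad = counts[counts < n_min]
    excluded = pd.DataFrame(
        {
            "species": bad.index,
            "n_records": bad.to_numpy(),
            "reason": f"fewer than {n_min} records",
        }
    ).reset_index(drop=True)
    kept = occ[~occ["species"].isin(set(bad.index))].reset_index(drop=True)
    return kept, excluded


def clean_season(
    occ: pd.DataFrame, min_dist_km: float = 1.0, n_min: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Thin then apply the minimum-record filter (single-season table)."""
    thinned = thin_spatial(occ, min_dist_km)
    return filter_min_records(thinned, n_min)
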