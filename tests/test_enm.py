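"""Ellipsoid niche models: MVE fitting, suitability surfaces, region clipping."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import ConvexHull

from cooccur.enm import (
    EllipsoidNicheModel,
    binarize_sdm,
    clip_to_region,
    constrained_region,
    ellipsoid_log_volume,
    extract_env_values,
    fit_mve,
    khachiyan_ellipsoid,
    mve_params,
    suitability_surface,
)
from cooccur.grid import EnvStack, FLOAT_NODATA, GridSpec
from cooccur.synthetic import true_suitable_mask


def oracle_min_logvol(X: np.ndarray, n_keep: int) -> float:
    """Exhaustive subset search with exact MVE per subset (hull-memoized)."""
    cache: dict[frozenset, float] = {}
    best = np.inf
    for subset in itertools.combinations(range(len(X)), n_keep):
        P = X[list(subset)]
        key = frozenset(np.asarray(subset)[ConvexHull(P).vertices])
        v = cache.get(key)
        if v is None:
            _, sigma, c, _ = mve_params(X[sorted(key)])
            v = ellipsoid_log_volume(sigma, c)
            cache[key] = v
        best = min(best, v)
    return best


class TestKhachiyan:
    def test_points_on_circle_give_unit_disk(self):
        th = np.linspace(0, 2 * np.pi, 13)[:-1]
        P = np.column_stack([np.cos(th), np.sin(th)])
        center, A = khachiyan_ellipsoid(P, tol=1e-9)
        np.testing.assert_allclose(center, 0, atol=1e-8)
        np.testing.assert_allclose(A, np.eye(2), atol=1e-6)

    @pytest.mark.parametrize("d", [2, 5])
    def test_encloses_all_points(self, rng, d):
        P = rng.standard_normal((40, d))
        center, A = khachiyan_ellipsoid(P)
        m2 = np.einsum("ij,ij->i", (P - center) @ A, P - center)
        assert m2.max() <= 1 + 1e-4

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError):
            khachiyan_ellipsoid(rng.standard_normal((2, 2)))


class TestEllipsoidNicheModel:
    def test_full_inclusion_when_tau_one(self, rng):
        X = rng.standard_normal((30, 3))
        m = fit_mve(X, tau=1.0)
        assert (m.mahalanobis_sq(X) <= m.cutoff_).all()

    def test_coverage_invariant(self, rng):
        X = rng.standard_normal((60, 4))
        m = fit_mve(X, tau=0.75)
        n_unique = len(np.unique(X, axis=0))
        covered = (m.mahalanobis_sq(np.unique(X, axis=0)) <= m.cutoff_).sum()
        assert covered >= int(np.ceil(0.75 * n_unique))

    def test_outliers_excluded(self, rng):
        inliers = rng.normal(size=(18, 2)) * 0.3
        outliers = np.array([[10.0, 10.0], [-12.0, 8.0]])
        X = np.vstack([inliers, outliers])
        m = fit_mve(X, tau=0.9)
        m2 = m.mahalanobis_sq(outliers)
        assert (m2 > m.cutoff_).all()

    def test_near_oracle_on_small_2d_instances(self, rng):
        # the full 20-instance sweep lives in the acceptance suite
        for _ in range(5):
            n = int(rng.integers(16, 21))
            X = rng.standard_normal((n, 2))
            m = fit_mve(X, tau=0.75)
            oracle = oracle_min_logvol(np.unique(X, axis=0), int(np.ceil(0.75 * n)))
            assert np.exp(m.log_volume_ - oracle) <= 1.01

    def test_errors(self, rng):
        with pytest.raises(ValueError, match="insufficient"):
            fit_mve(rng.standard_normal((3, 4)))
        X = rng.standard_normal((20, 3))
        X[:, 1] = 5.0  # constant layer
        with pytest.raises(ValueError, match="degenerate"):
            fit_mve(X)
        X = rng.standard_normal((20, 2))
        X = np.column_stack([X, X[:, 0] * 2 - X[:, 1]])  # collinear layer
        with pytest.raises(ValueError, match="singular|collinear"):
            fit_mve(X)
        with pytest.raises(ValueError):
            fit_mve(rng.standard_normal((20, 2)), tau=0.4)

    def test_moment_fallback_small_n(self, rng):
        X = rng.standard_normal((8, 5))  # n < 2 d
        m = fit_mve(X, tau=1.0)
        assert m.method_ == "moment"
        assert (m.mahalanobis_sq(X) <= m.cutoff_).all()

    def test_sklearn_params_roundtrip(self):
        m = EllipsoidNicheModel(tau=0.8)
        assert m.get_params()["tau"] == 0.8
        m.set_params(tau=0.9)
        assert m.tau == 0.9


def tiny_stack() -> EnvStack:
    grid = GridSpec(4, 3, 1.0)
    a = np.arange(12, dtype=float).reshape(3, 4)
    b = np.array([x * x % 7 for x in range(12)], dtype=float).reshape(3, 4)
    return EnvStack(["l0", "l1"], np.stack([a, b]), grid)


class TestRasterProjection:
    def test_extract_known_values(self):
        stack = tiny_stack()
        pts = pd.DataFrame({"species": "s", "x": [0.5, 3.5], "y": [0.5, 2.5],
                            "month": 6})
        V = extract_env_values(pts, stack)
        np.testing.assert_allclose(V, [[0, 0], [11, 121 % 7]])

    def test_outside_and_nodata_dropped(self):
        stack = tiny_stack()
        stack.data[0, 0, 0] = FLOAT_NODATA
        pts = pd.DataFrame(
            {"species": "s", "x": [0.5, 9.0, 1.5], "y": [0.5, 0.5, 0.5], "month": 6}
        )
        V = extract_env_values(pts, stack)
        assert V.shape == (1, 2)

    def test_all_nodata_raises_with_species_name(self):
        stack = tiny_stack()
        pts = pd.DataFrame({"species": "lost", "x": [-5.0], "y": [0.5], "month": 6})
        with pytest.raises(ValueError, match="lost"):
            extract_env_values(pts, stack)

    def test_suitability_center_is_one_and_monotone(self, rng):
        stack = tiny_stack()
        E, _ = stack.env_matrix()
        m = fit_mve(E, tau=1.0)
        s = suitability_surface(m, stack)
        m2 = m.mahalanobis_sq(E)
        vals = s.values[stack.valid_mask]
        assert vals.max() == pytest.approx(1.0)
        order = np.argsort(m2)
        assert (np.diff(vals[order]) <= 1e-12).all()

    def test_all_nodata_stack_propagates(self):
        stack = tiny_stack()
        m = fit_mve(stack.env_matrix()[0], tau=1.0)
        stack.data[:] = FLOAT_NODATA
        s = suitability_surface(m, stack)
        assert (s.values == FLOAT_NODATA).all()

    def test_binary_covers_training_fraction(self, rng):
        stack = tiny_stack()
        E, ji = stack.env_matrix()
        m = fit_mve(E, tau=0.75)
        b = binarize_sdm(m, stack)
        frac = (b.values[ji[:, 0], ji[:, 1]] == 1).mean()
        assert frac >= 0.75

    def test_infinite_cutoff_fills_valid_cells(self):
        stack = tiny_stack()
        m = fit_mve(stack.env_matrix()[0], tau=1.0)
        m.cutoff_ = np.inf
        b = binarize_sdm(m, stack)
        assert (b.values[stack.valid_mask] == 1).all()

    def test_layer_mismatch_raises(self):
        stack = tiny_stack()
        m = fit_mve(np.random.default_rng(0).standard_normal((10, 3)), tau=1.0)
        with pytest.raises(ValueError, match="layers"):
            suitability_surface(m, stack)


class TestRegionClipping:
    def test_constrained_single_slope(self, small_system, small_config):
        stack, niches, occ, regions = small_system
        niche = next(n for n in niches if n.slope in ("pacific", "caribbean"))
        pts = occ[(occ["species"] == niche.species_id) & (occ["month"] == niche.month)]
        E = extract_env_values(pts, stack)
        model = fit_mve(E, tau=0.75)
        b = binarize_sdm(model, stack)
        region = constrained_region(regions, pts)
        clipped = clip_to_region(b, region, "constrained")
        barrier = small_config.barrier_column
        off_slope = (
            clipped.values[:, barrier:]
            if niche.slope == "pacific"
            else clipped.values[:, :barrier]
        )
        assert (off_slope == clipped.nodata).all()

    def test_both_slopes_equals_neutral(self, small_system):
        stack, niches, occ, regions = small_system
        for niche in niches:
            pts = occ[
                (occ["species"] == niche.species_id) & (occ["month"] == niche.month)
            ]
            slopes = regions.slope_of_points(pts["x"].to_numpy(), pts["y"].to_numpy())
            if len(slopes) == 2:
                break
        else:
            pytest.skip("no two-slope species in fixture")
        E = extract_env_values(pts, stack)
        model = fit_mve(E, tau=0.75)
        b = binarize_sdm(model, stack)
        neutral = clip_to_region(b, regions.domain, "neutral")
        constrained = clip_to_region(b, constrained_region(regions, pts), "constrained")
        np.testing.assert_array_equal(neutral.values, constrained.values)

    def test_constrained_subset_of_neutral(self, small_system):
        stack, niches, occ, regions = small_system
        for niche in niches[:8]:
            pts = occ[
                (occ["species"] == niche.species_id) & (occ["month"] == niche.month)
            ]
            model = fit_mve(extract_env_values(pts, stack), tau=0.75)
            b = binarize_sdm(model, stack)
            neutral = clip_to_region(b, regions.domain, "neutral")
            constrained = clip_to_region(
                b, constrained_region(regions, pts), "constrained"
            )
            n_sup = neutral.values == 1
            c_sup = constrained.values == 1
            assert not (c_sup & ~n_sup).any()

    def test_empty_intersection_raises(self, small_system):
        from shapely.geometry import box

        stack, _, occ, regions = small_system
        pts = occ[occ["species"] == occ["species"].iloc[0]]
        model = fit_mve(extract_env_values(pts, stack), tau=0.75)
        b = binarize_sdm(model, stack)
        with pytest.raises(ValueError):
            clip_to_region(b, box(500, 500, 600, 600), "neutral")


class TestRecovery:
    def test_fitted_support_covers_true_suitable_cells(self, small_system, small_config):
        """With full detection and tau=1 the fitted envelope should recover
        nearly all truly suitable cells of the generative ellipsoid."""
        stack, niches, occ, _ = small_system  # detection_rate = 1
        checked = 0
        for niche in niches:
            if niche.slope != "both":
                continue
            pts = occ[
                (occ["species"] == niche.species_id) & (occ["month"] == niche.month)
            ]
            model = fit_mve(extract_env_values(pts, stack), tau=1.0)
            b = binarize_sdm(model, stack)
            true_mask = true_suitable_mask(niche, stack, small_config)
            recovered = (b.values == 1) & true_mask
            assert recovered.sum() >= 0.95 * true_mask.sum()
            checked += 1
        assert checked >= 2
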