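"""Niche similarity statistics: Schoener's D, nulls, group tests."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cooccur.grid import FLOAT_NODATA, GridSpec, Raster
from cooccur.overlap import (
    NullDistribution,
    category_comparisons,
    effort_bias_check,
    fisher_exact_2xc,
    migrant_subsample_test,
    observed_vs_null_test,
    overlap_table,
    randomized_null,
    schoener_d,
)


def raster(values, nodata=FLOAT_NODATA) -> Raster:
    v = np.asarray(values, dtype=float)
    return Raster(v, GridSpec(v.shape[1], v.shape[0], 1.0), nodata=nodata)


class TestSchoenerD:
    def test_identity(self, rng):
        r = raster(rng.random((5, 5)))
        assert schoener_d(r, r) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        a = raster([[1.0, 1.0, 0.0, 0.0]])
        b = raster([[0.0, 0.0, 1.0, 1.0]])
        assert schoener_d(a, b) == pytest.approx(0.0)

    def test_hand_example_half(self):
        p = raster([[0.5, 0.5, 0.0, 0.0]])
        q = raster([[0.25, 0.25, 0.25, 0.25]])
        assert schoener_d(p, q) == pytest.approx(0.5)

    def test_symmetry_and_range_on_random_pairs(self, rng):
        for _ in range(100):
            a = raster(rng.random((6, 6)))
            b = raster(rng.random((6, 6)))
            d_ab, d_ba = schoener_d(a, b), schoener_d(b, a)
            assert abs(d_ab - d_ba) < 1e-12
            assert 0.0 <= d_ab <= 1.0

    def test_disjoint_valid_regions_score_zero(self):
        a = raster([[1.0, 1.0, FLOAT_NODATA, FLOAT_NODATA]])
        b = raster([[FLOAT_NODATA, FLOAT_NODATA, 1.0, 1.0]])
        assert schoener_d(a, b) == pytest.approx(0.0)

    def test_all_zero_surface_raises(self):
        with pytest.raises(ValueError):
            schoener_d(raster([[0.0, 0.0]]), raster([[1.0, 1.0]]))

    def test_geometry_mismatch_raises(self):
        with pytest.raises(ValueError):
            schoener_d(raster(np.ones((2, 2))), raster(np.ones((3, 3))))


class TestOverlapTable:
    def test_residents_only_with_categories(self, rng):
        june = {"a": raster(rng.random((4, 4))), "b": raster(rng.random((4, 4)))}
        december = {"a": june["a"], "m": raster(rng.random((4, 4)))}
        records = overlap_table(
            june, december, categories={"a": "stable"}, point_counts={"a": (12, 9)}
        )
        assert list(records["species"]) == ["a"]  # migrant-like m excluded
        assert records["D"].iloc[0] == pytest.approx(1.0)
        assert records["category"].iloc[0] == "stable"
        assert records["delta_points"].iloc[0] == 3


class TestRandomizedNull:
    def make_surfaces(self, rng, n=5):
        june = {f"s{i}": raster(rng.random((4, 4))) for i in range(n)}
        december = {f"s{i}": raster(rng.random((4, 4))) for i in range(n)}
        return june, december

    def test_deterministic_and_no_self_pairs(self, rng):
        june, december = self.make_surfaces(rng)
        a = randomized_null(june, december, n_draws=200, seed=3)
        b = randomized_null(june, december, n_draws=200, seed=3)
        np.testing.assert_array_equal(a.draws, b.draws)
        assert all(i != j for i, j in a.pairs)

    def test_degenerate_identical_surfaces(self, rng):
        shared = raster(rng.random((4, 4)))
        june = {f"s{i}": shared for i in range(3)}
        december = {f"s{i}": shared for i in range(3)}
        null = randomized_null(june, december, n_draws=50, seed=0)
        np.testing.assert_allclose(null.draws, 1.0)

    def test_too_few_species_rejected(self, rng):
        june, december = self.make_surfaces(rng, n=1)
        with pytest.raises(ValueError):
            randomized_null(june, december, n_draws=10, seed=0)


class TestObservedVsNull:
    def test_identical_samples(self):
        vals = np.array([0.1, 0.5, 0.9])
        out = observed_vs_null_test(vals, NullDistribution(vals.copy(), 0))
        assert out["t"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_strong_separation(self, rng):
        obs = 0.9 + rng.normal(0, 1e-4, 100)
        nul = 0.5 + rng.normal(0, 1e-4, 100)
        out = observed_vs_null_test(obs, NullDistribution(nul, 0))
        assert out["p"] < 1e-6 and out["t"] > 0

    def test_matches_textbook_welch(self, rng):
        x = rng.normal(0.8, 0.05, 10)
        y = rng.normal(0.6, 0.12, 10)
        out = observed_vs_null_test(x, NullDistribution(y, 0))
        vx, vy = x.var(ddof=1) / 10, y.var(ddof=1) / 10
        t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / 9 + vy**2 / 9)
        assert out["t"] == pytest.approx(t)
        assert out["df"] == pytest.approx(df)
        assert out["ci95_observed"] > 0


class TestCategoryComparisons:
    def records(self, stable, diffuse):
        return pd.DataFrame(
            {
                "species": [f"s{i}" for i in range(len(stable) + len(diffuse))],
                "D": stable + diffuse,
                "category": ["stable"] * len(stable) + ["diffuse"] * len(diffuse),
                "delta_points": 0,
                "mode": "neutral",
            }
        )

    def test_identical_multisets_give_p_one(self):
        out = category_comparisons(self.records([0.1, 0.5, 0.9], [0.1, 0.5, 0.9]))
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_extreme_separation_matches_exact_enumeration(self):
        out = category_comparisons(self.records([1.0, 2.0, 3.0], [4.0, 5.0, 6.0]))
        # all stable ranks below all diffuse: U = 0; exact two-sided
        # p = 2 * 1 / C(6,3) = 0.1
        assert out["W"].iloc[0] == pytest.approx(0.0)
        assert out["p"].iloc[0] == pytest.approx(0.1)

    def test_ci_contains_sample_mean(self):
        out = category_comparisons(self.records([0.2, 0.4, 0.9], [0.3, 0.5]))
        assert abs(out["mean_a"].iloc[0] - np.mean([0.2, 0.4, 0.9])) <= 1e-12

    def test_single_category_rejected(self):
        df = self.records([0.1, 0.2], [])
        with pytest.raises(ValueError):
            category_comparisons(df)


class TestEffortBias:
    def test_monotone_decreasing_rho(self):
        records = pd.DataFrame(
            {
                "species": list("abcde"),
                "D": [0.9, 0.8, 0.7, 0.6, 0.5],
                "category": "stable",
                "delta_points": [1, 2, 3, 4, 5],
                "mode": "neutral",
            }
        )
        out = effort_bias_check(records)
        assert out["rho"] == pytest.approx(-1.0)

    def test_too_few_records_rejected(self):
        records = pd.DataFrame(
            {"species": ["a", "b"], "D": [0.5, 0.6], "category": "none",
             "delta_points": [1, 2], "mode": "neutral"}
        )
        with pytest.raises(ValueError, match="at least 3"):
            effort_bias_check(records)

    def test_constant_input_reported_undefined(self):
        records = pd.DataFrame(
            {"species": list("abcd"), "D": [0.5] * 4, "category": "none",
             "delta_points": [1, 2, 3, 4], "mode": "neutral"}
        )
        out = effort_bias_check(records)
        assert np.isnan(out["rho"]) and "note" in out


class TestFisherExact:
    def test_two_by_two_hand_example(self):
        from scipy.stats import fisher_exact

        table = np.array([[3, 1], [1, 3]])
        assert fisher_exact_2xc(table) == pytest.approx(0.4857, abs=1e-3)
        assert fisher_exact_2xc(table) == pytest.approx(
            fisher_exact(table)[1], rel=1e-9
        )

    def test_identical_rows_give_p_one(self):
        assert fisher_exact_2xc(np.array([[5, 5, 5], [5, 5, 5]])) == pytest.approx(1.0)

    def test_two_by_three_matches_r_fisher_test(self):
        table = np.array([[8, 2, 4], [3, 7, 5]])
        p_mine = fisher_exact_2xc(table)
        r_code = (
            "cat(fisher.test(matrix(c(8,3,2,7,4,5), nrow=2))$p.value)"
        )
        try:
            res = subprocess.run(
                ["Rscript", "-e", r_code], capture_output=True, text=True, timeout=120
            )
            p_r = float(res.stdout.strip())
        except (FileNotFoundError, ValueError, subprocess.TimeoutExpired):
            pytest.skip("Rscript unavailable")
        assert p_mine == pytest.approx(p_r, rel=1e-6)

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2xc(np.array([[1, 2, 3]]))
        with pytest.raises(ValueError):
            fisher_exact_2xc(np.array([[1, -2], [3, 4]]))


class TestMigrantSubsample:
    def make_records(self, rng, n=40):
        cats = rng.choice(["stable", "split", "diffuse"], size=n, p=[0.3, 0.3, 0.4])
        return pd.DataFrame(
            {
                "species": [f"s{i}" for i in range(n)],
                "D": rng.random(n),
                "category": cats,
                "delta_points": 0,
                "mode": "neutral",
            }
        )

    def test_null_behaviour_and_determinism(self, rng):
        records = self.make_records(rng)
        mig = list(records["species"].sample(10, random_state=1))
        a = migrant_subsample_test(records, mig, n_subsamples=100, seed=5)
        b = migrant_subsample_test(records, mig, n_subsamples=100, seed=5)
        assert a == b
        assert 0.0 <= a["p"] <= 1.0
        assert sum(a["migrant_counts"]) == 10

    def test_small_migrant_set_rejected(self, rng):
        records = self.make_records(rng)
        with pytest.raises(ValueError):
            migrant_subsample_test(records, ["s0", "s1"], n_subsamples=10, seed=0)


@settings(deadline=None, max_examples=40)
@given(st.integers(0, 2**31 - 1))
def test_schoener_d_bounds_property(seed):
    rng = np.random.default_rng(seed)
    a = raster(rng.random((4, 4)) + 1e-9)
    b = raster(rng.random((4, 4)) + 1e-9)
    d = schoener_d(a, b)
    assert 0.0 <= d <= 1.0
    assert d == pytest.approx(schoener_d(b, a), abs=1e-12)
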