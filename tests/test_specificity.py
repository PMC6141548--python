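"""t-test screens, permutation null, and set comparison."""

import itertools
import math

import numpy as np
import pytest

from circage import (
    NumericError,
    compare_sets,
    group_biased,
    permutation_test,
    spatial_specific,
    two_group_t_test,
)


def welch_oracle(x, y):
    """Textbook Welch statistic and Satterthwaite df, coded independently."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    from scipy.stats import t as tdist

    return t, 2 * tdist.sf(abs(t), df)


class TestTwoGroupTTest:
    def test_identical_groups(self):
        t, p = two_group_t_test([1, 2, 3], [1, 2, 3])
        assert (t, p) == (0.0, 1.0)

    def test_matches_welch_oracle(self):
        x, y = [1, 2, 3, 4], [2, 3, 4, 5]
        t, p = two_group_t_test(x, y)
        t0, p0 = welch_oracle(x, y)
        assert abs(t - t0) < 1e-12 and abs(p - p0) < 1e-12

    def test_random_inputs_match_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=rng.integers(3, 12))
            y = rng.normal(loc=0.5, size=rng.integers(3, 12))
            t, p = two_group_t_test(x, y)
            t0, p0 = welch_oracle(x, y)
            assert abs(t - t0) < 1e-10 and abs(p - p0) < 1e-10

    def test_distinct_constant_groups_degenerate(self):
        t, p = two_group_t_test([2.0, 2.0, 2.0], [5.0, 5.0])
        assert p == 0.0 and t == -np.inf
        t, p = two_group_t_test([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_paired_uses_differences(self):
        x, y = [1.0, 2.0, 3.0, 4.0], [0.5, 1.5, 2.5, 3.5]
        t, p = two_group_t_test(x, y, paired=True)
        assert t == np.inf and p == 0.0  # constant difference of +0.5
        with pytest.raises(ValueError):
            two_group_t_test([1, 2, 3], [1, 2], paired=True)

    def test_tiny_groups_rejected(self):
        with pytest.raises(NumericError):
            two_group_t_test([1.0], [1.0, 2.0])


class TestSpatial:
    def planted(self, design32, make_matrix_fn, rng, n_noise=50):
        region = design32.data["region"].to_numpy()
        rows = [np.where(region == "CB", 100.0, 1.0) + rng.normal(0, 0.05, 32)]
        rows += [10 + rng.normal(0, 1, 32) for _ in range(n_noise)]
        return make_matrix_fn(np.abs(rows), design32.sample_ids)

    def test_planted_cb_row_called_cb(self, design32, make_matrix_fn, rng):
        m = self.planted(design32, make_matrix_fn, rng)
        res = spatial_specific(m, design32, alpha=0.01)
        planted = res[(res["circ_id"] == m.circ_ids[0]) & res["called"]]
        assert len(planted) == 1
        assert planted.iloc[0]["enriched_group"] == "CB"

    def test_at_most_one_region_per_circ(self, design32, make_matrix_fn, rng):
        m = self.planted(design32, make_matrix_fn, rng, n_noise=200)
        res = spatial_specific(m, design32, alpha=0.05)
        per_circ = res[res["called"]].groupby("circ_id").size()
        assert (per_circ <= 1).all()

    def test_vs_each_calls_subset_of_one_vs_rest(self, design32, make_matrix_fn, rng):
        m = self.planted(design32, make_matrix_fn, rng, n_noise=300)
        ovr = spatial_specific(m, design32, alpha=0.05, mode="one_vs_rest")
        strict = spatial_specific(m, design32, alpha=0.05, mode="vs_each")
        called = lambda df: set(df.loc[df["called"], "circ_id"])
        assert called(strict) <= called(ovr)

    def test_region_with_single_sample_is_error(self, design32, make_matrix_fn, rng):
        from circage import SampleTable

        small = SampleTable(data=design32.data.iloc[[0, 4, 5, 6, 7]])
        m = make_matrix_fn(rng.random((3, 5)) + 1, small.sample_ids)
        with pytest.raises(NumericError, match="fewer than 2"):
            spatial_specific(m, small)


class TestGroupBiased:
    def test_shifted_male_columns_called_male(self, design32, make_matrix_fn, rng):
        sex = design32.data["sex"].to_numpy()
        row = 10.0 + np.where(sex == "M", 10.0, 0.0) + rng.normal(0, 0.1, 32)
        res = group_biased(make_matrix_fn(row[None, :], design32.sample_ids),
                           design32, "sex")
        assert res["called"].iloc[0] and res["enriched_group"].iloc[0] == "M"

    def test_null_call_rate_close_to_alpha(self, design32, make_matrix_fn, rng):
        m = make_matrix_fn(np.abs(rng.normal(20, 3, (2000, 32))), design32.sample_ids)
        res = group_biased(m, design32, "sex", alpha=0.05, log_transform=False)
        frac = res["called"].mean()
        assert 0.03 <= frac <= 0.07  # binomial error around 0.05

    def test_rows_match_two_group_t_test(self, design32, make_matrix_fn, rng):
        m = make_matrix_fn(rng.integers(1, 100, (5, 32)), design32.sample_ids)
        res = group_biased(m, design32, "age")
        age = design32.data["age_years"].to_numpy()
        x = np.log2(m.values + 1.0)
        for i in range(5):
            t, p = two_group_t_test(x[i, age == 20], x[i, age == 10])
            assert np.isclose(res["t_stat"].iloc[i], t)
            assert np.isclose(res["p_t"].iloc[i], p)


class TestPermutation:
    def test_constant_row_has_p_one(self, design32, make_matrix_fn):
        m = make_matrix_fn(np.full((1, 32), 9.0), design32.sample_ids)
        p = permutation_test(m, design32, "sex", n_perm=200, seed=1)
        assert p.iloc[0] == 1.0

    def test_same_seed_is_deterministic(self, design32, make_matrix_fn, rng):
        m = make_matrix_fn(rng.integers(0, 40, (20, 32)), design32.sample_ids)
        p1 = permutation_test(m, design32, "sex", n_perm=500, seed=7)
        p2 = permutation_test(m, design32, "sex", n_perm=500, seed=7)
        assert (p1 == p2).all()

    def test_add_one_estimator_bounds(self, design32, make_matrix_fn, rng):
        m = make_matrix_fn(rng.integers(0, 40, (50, 32)), design32.sample_ids)
        p = permutation_test(m, design32, "age", n_perm=99, seed=3)
        assert (p >= 1 / 100).all() and (p <= 1.0).all()

    def test_exact_three_vs_three_matches_enumeration(self):
        """All C(6,3)=20 label splits, against an independent enumeration."""
        import pandas as pd

        from circage import JunctionCountMatrix, SampleTable

        rows = np.array([[3.0, 1.0, 4.0, 10.0, 12.0, 9.0],
                         [5.0, 5.0, 5.0, 5.0, 5.0, 5.1]])
        sample_ids = [f"s{i}" for i in range(6)]
        design = SampleTable(data=pd.DataFrame(
            {"region": ["CB"] * 6, "sex": ["M"] * 3 + ["F"] * 3,
             "age_years": [10] * 6},
            index=pd.Index(sample_ids, name="sample_id"),
        ))
        m = JunctionCountMatrix(
            counts=pd.DataFrame(rows, index=["c1", "c2"], columns=sample_ids)
        )
        p = permutation_test(m, design, "sex", exact=True, log_transform=False)

        x = rows
        for row, p_obs in zip(x, p):
            # independent oracle: enumerate every split of 6 into 3 vs 3
            obs = row[3:].mean() - row[:3].mean()  # M sorts after F
            count = 0
            total = 0
            for idx in itertools.combinations(range(6), 3):
                mask = np.zeros(6, bool)
                mask[list(idx)] = True
                stat = row[mask].mean() - row[~mask].mean()
                total += 1
                if abs(stat) >= abs(obs) - 1e-12:
                    count += 1
            assert np.isclose(p_obs, count / total)

    def test_invalid_n_perm(self, design32, make_matrix_fn):
        m = make_matrix_fn(np.ones((1, 32)), design32.sample_ids)
        with pytest.raises(ValueError):
            permutation_test(m, design32, "sex", n_perm=0)


class TestCompareSets:
    @pytest.mark.parametrize(
        "a,b,inter,ratio",
        [
            ({"a", "b", "c"}, {"b", "c", "d"}, 2, 2 / 3),
            ({"a"}, {"b"}, 0, 0.0),
            ({"a", "b"}, {"a", "b"}, 2, 1.0),
        ],
    )
    def test_overlap_counts(self, a, b, inter, ratio):
        c = compare_sets(a, b)
        assert (c.intersection, c.overlap_ratio) == (inter, ratio)
        assert c.intersection <= min(c.size_a, c.size_b)
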