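import numpy as np
import pandas as pd
import pytest

from nacmap import (
    CentralityMap,
    RegionAtlas,
    RegionalDistribution,
    chi_square_homogeneity,
    median_split,
    menstrual_phase,
    permutation_region_test,
)
from nacmap.classification import NODE_TYPES


def dist_from_counts(counts_by_region, node_type="global_hub"):
    regions = [f"R{i}" for i in range(len(counts_by_region))]
    df = pd.DataFrame(0, index=regions, columns=list(NODE_TYPES))
    df[node_type] = counts_by_region
    df["local_node"] = 10  # make all regions non-empty
    return RegionalDistribution(counts=df)


def pearson_chi2_oracle(table):
    """Brute-force sum over cells of (O - E)^2 / E."""
    table = np.asarray(table, float)
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows * cols / table.sum()
    return float((((table - expected) ** 2) / expected).sum())


class TestChiSquare:
    def test_identical_tables_give_zero(self):
        d = dist_from_counts([3, 5, 2])
        stat, df, p_raw, p_corr = chi_square_homogeneity(d, d, "global_hub")
        assert stat == pytest.approx(0.0)
        assert p_raw == pytest.approx(1.0)

    def test_hand_example_2x2(self):
        # [[10, 20], [20, 10]]: Pearson statistic 6.667, p ~ .0098
        d1 = dist_from_counts([10, 20])
        d2 = dist_from_counts([20, 10])
        stat, df, p_raw, p_corr = chi_square_homogeneity(d1, d2, "global_hub")
        assert stat == pytest.approx(6.667, abs=1e-3)
        assert df == 1
        assert p_raw == pytest.approx(0.0098, abs=2e-4)
        assert p_corr == pytest.approx(min(1.0, 4 * p_raw))

    def test_bonferroni_times_four(self):
        d1 = dist_from_counts([8, 2, 5, 1])
        d2 = dist_from_counts([2, 8, 1, 5])
        _, _, p_raw, p_corr = chi_square_homogeneity(d1, d2, "global_hub")
        assert p_corr == min(1.0, 4 * p_raw)

    def test_empty_regions_dropped_with_reduced_df(self):
        d1 = dist_from_counts([5, 0, 3, 0])
        d2 = dist_from_counts([2, 0, 6, 0])
        with pytest.warns(UserWarning, match="dropped"):
            stat, df, p_raw, _ = chi_square_homogeneity(d1, d2, "global_hub")
        assert df == 1  # two informative regions -> df = 2 - 1

    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = rng.integers(2, 6)
            c1 = rng.integers(1, 9, k)
            c2 = rng.integers(1, 9, k)
            stat, _, _, _ = chi_square_homogeneity(
                dist_from_counts(c1), dist_from_counts(c2), "global_hub"
            )
            assert stat == pytest.approx(pearson_chi2_oracle([c1, c2]), rel=1e-10)


def synthetic_maps(rng, n_sub, n_nodes, shift=None):
    maps = []
    for _ in range(n_sub):
        v = rng.random(n_nodes) + 0.5
        w = rng.random(n_nodes) + 0.5
        if shift is not None:
            w = w + shift
        maps.append(
            CentralityMap(nac0=100 * v / v.sum(), nac1=100 * w / w.sum())
        )
    return maps


class TestPermutationTest:
    @pytest.fixture()
    def atlas(self):
        return RegionAtlas(labels=[f"R{i % 4}" for i in range(32)])

    def test_fixed_seed_reproducible(self, atlas):
        rng = np.random.default_rng(1)
        maps = synthetic_maps(rng, 12, 32)
        labels = ["a"] * 6 + ["b"] * 6
        p1 = permutation_region_test(maps, labels, atlas, n_perm=200, seed=9)
        p2 = permutation_region_test(maps, labels, atlas, n_perm=200, seed=9)
        pd.testing.assert_frame_equal(p1, p2)

    def test_observed_differences_antisymmetric_under_label_swap(self, atlas):
        rng = np.random.default_rng(2)
        maps = synthetic_maps(rng, 10, 32)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        fwd = permutation_region_test(maps, labels, atlas, n_perm=100, seed=3)
        rev = permutation_region_test(
            maps, labels, atlas, n_perm=100, seed=3, groups=("b", "a")
        )
        np.testing.assert_allclose(
            fwd["diff_percent"], -rev["diff_percent"], atol=1e-12
        )

    def test_label_symmetry_of_p_values(self, atlas):
        # swapping the group orientation negates the observed differences and
        # reproduces the direction-matched tail p exactly (same null sample)
        rng = np.random.default_rng(3)
        maps = synthetic_maps(rng, 10, 32)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        n_perm = 500
        fwd, null = permutation_region_test(
            maps, labels, atlas, n_perm=n_perm, seed=4, return_null=True
        )
        rev = permutation_region_test(
            maps, labels, atlas, n_perm=n_perm, seed=4, groups=("b", "a")
        )
        obs = fwd["diff_percent"].to_numpy().reshape(null.shape[1:])
        mirrored_tail = (null >= -obs).sum(axis=0).ravel() / n_perm
        np.testing.assert_allclose(rev["p_greater"], mirrored_tail, atol=1e-12)
        np.testing.assert_allclose(
            rev["p_less"], (null <= -obs).sum(axis=0).ravel() / n_perm, atol=1e-12
        )

    def test_degenerate_all_ties_give_p_one(self, atlas):
        maps = synthetic_maps(np.random.default_rng(4), 1, 32)
        same = [CentralityMap(nac0=maps[0].nac0, nac1=maps[0].nac1) for _ in range(8)]
        labels = ["a"] * 4 + ["b"] * 4
        out = permutation_region_test(same, labels, atlas, n_perm=100, seed=0)
        assert (out["p"] == 1.0).all()
        assert (out["diff_percent"] == 0.0).all()

    def test_low_n_perm_warns_and_small_group_rejected(self, atlas):
        rng = np.random.default_rng(5)
        maps = synthetic_maps(rng, 8, 32)
        with pytest.warns(UserWarning, match="resolution"):
            permutation_region_test(maps, ["a"] * 4 + ["b"] * 4, atlas, n_perm=50, seed=0)
        with pytest.raises(ValueError):
            permutation_region_test(maps, ["a"] + ["b"] * 7, atlas, n_perm=100, seed=0)

    def test_p_values_are_multiples_of_resolution(self, atlas):
        rng = np.random.default_rng(6)
        maps = synthetic_maps(rng, 10, 32)
        out = permutation_region_test(
            maps, ["a"] * 5 + ["b"] * 5, atlas, n_perm=250, seed=1
        )
        steps = out["p"].to_numpy() * 250
        np.testing.assert_allclose(steps, np.round(steps), atol=1e-9)


class TestMedianSplit:
    def test_even_split(self):
        low, high = median_split([1.0, 2.0, 3.0, 4.0])
        assert sorted(low) == [0, 1] and sorted(high) == [2, 3]

    def test_odd_count_puts_middle_in_high(self):
        low, high = median_split([5.0, 1.0, 3.0])
        assert list(low) == [1]
        assert sorted(high) == [0, 2]

    def test_ties_split_by_stable_order(self):
        # the tied median value may appear in both halves
        values = [0.95, 0.95, 0.90, 0.95, 0.99, 0.95]
        low, high = median_split(values)
        assert len(low) == 3 and len(high) == 3
        assert 2 in low  # smallest value is in the low half
        assert 4 in high  # largest value is in the high half
        tied = [i for i in range(6) if values[i] == 0.95]
        assert set(tied) & set(low) and set(tied) & set(high)

    def test_partition_and_ordering(self):
        rng = np.random.default_rng(7)
        v = rng.normal(0.95, 0.03, 101)
        low, high = median_split(v)
        assert len(low) == 50 and len(high) == 51
        assert set(low) | set(high) == set(range(101))
        assert v[low].max() <= v[high].min()


class TestMenstrualPhase:
    @pytest.mark.parametrize(
        "day,phase",
        [(1, "follicular"), (6, "follicular"), (14, "follicular"),
         (15, "luteal"), (28, "luteal"), (29, "unknown"), (39, "unknown")],
    )
    def test_phase_rule(self, day, phase):
        assert menstrual_phase(day) == phase

    def test_invalid_day_rejected(self):
        with pytest.raises(ValueError):
            menstrual_phase(0)
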