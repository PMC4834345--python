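import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import macanet as mn
from conftest import random_interaction_matrix


def _attrs_from(ids, gender=None, age=None, matriline=None):
    n = len(ids)
    df = pd.DataFrame(
        {
            "gender": gender if gender is not None else ["F"] * n,
            "age": age if age is not None else np.arange(1.0, n + 1),
            "matriline": matriline if matriline is not None else [1.0] * n,
            "hierarchy": np.arange(1.0, n + 1),
        },
        index=pd.Index(ids, name="id"),
    )
    return mn.AttributeTable(df)


def brute_force_moran(w, x):
    n = len(x)
    xbar = x.mean()
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                num += w[i, j] * (x[i] - xbar) * (x[j] - xbar)
                s0 += w[i, j]
    return (n / s0) * num / sum((xi - xbar) ** 2 for xi in x)


class TestCategoricalHomophily:
    def _four_node(self):
        # 2 F (n1,n2), 2 M (n3,n4); w12=w21=3, w34=w43=1, w13=2
        counts = np.array(
            [[0, 3, 2, 0], [3, 0, 0, 0], [0, 0, 0, 1], [0, 0, 1, 0]]
        )
        ids = ["n1", "n2", "n3", "n4"]
        m = mn.InteractionMatrix(ids, counts)
        attrs = _attrs_from(ids, gender=["F", "F", "M", "M"])
        return m, attrs

    def test_hand_computed_statistic(self):
        m, attrs = self._four_node()
        res = mn.categorical_homophily_test(m, attrs, "gender", n_perm=99, seed=0)
        # within mean = (3+3+1+1)/4 = 2.0; between mean = 2/8 = 0.25
        assert res.statistic == pytest.approx(0.25 - 2.0)

    def test_uniform_weights_give_zero(self):
        ids = list("abcd")
        counts = np.full((4, 4), 2)
        np.fill_diagonal(counts, 0)
        m = mn.InteractionMatrix(ids, counts)
        attrs = _attrs_from(ids, gender=["F", "F", "M", "M"])
        res = mn.categorical_homophily_test(m, attrs, "gender", n_perm=49, seed=1)
        assert res.statistic == 0.0

    def test_small_level_rejected(self):
        ids = list("abc")
        m = random_interaction_matrix(np.random.default_rng(0), 3)
        m = mn.InteractionMatrix(ids, m.counts)
        attrs = _attrs_from(ids, gender=["F", "M", "M"])
        with pytest.raises(mn.DegenerateGroupError):
            mn.categorical_homophily_test(m, attrs, "gender", n_perm=9)

    def test_statistic_invariant_under_label_swap(self):
        """The statistic depends on the partition, not the label names."""
        m, attrs = self._four_node()
        swapped = _attrs_from(m.ids, gender=["M", "M", "F", "F"])
        a = mn.categorical_homophily_test(m, attrs, "gender", n_perm=19, seed=0)
        b = mn.categorical_homophily_test(m, swapped, "gender", n_perm=19, seed=0)
        assert a.statistic == pytest.approx(b.statistic)

    def test_missing_levels_excluded(self):
        ids = list("abcde")
        counts = np.zeros((5, 5), dtype=int)
        counts[0, 1] = counts[1, 0] = 3
        counts[2, 3] = counts[3, 2] = 1
        m = mn.InteractionMatrix(ids, counts)
        attrs = _attrs_from(ids, gender=["F", "F", "M", "M", "F"])
        attrs.data.loc["e", "matriline"] = np.nan
        attrs.data.loc[["a", "b"], "matriline"] = 1.0
        attrs.data.loc[["c", "d"], "matriline"] = 2.0
        res = mn.categorical_homophily_test(m, attrs, "matriline", n_perm=19, seed=0)
        assert res.n_individuals == 4


class TestMoranI:
    def test_reciprocal_pair_is_minus_one(self):
        m = mn.InteractionMatrix(["a", "b"], np.array([[0, 1], [1, 0]]))
        assert mn.moran_i(m, np.array([3.0, 9.0])) == pytest.approx(-1.0)

    def test_two_disjoint_dyads_is_plus_one(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 1] = counts[1, 0] = 1
        counts[2, 3] = counts[3, 2] = 1
        m = mn.InteractionMatrix(list("abcd"), counts)
        assert mn.moran_i(m, np.array([5.0, 5.0, 11.0, 11.0])) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        m = random_interaction_matrix(rng, 8)
        x = rng.normal(size=8)
        assert mn.moran_i(m, x) == pytest.approx(
            brute_force_moran(m.counts.astype(float), x), abs=1e-12
        )

    @given(st.integers(0, 10_000), st.floats(0.1, 50), st.floats(-100, 100))
    def test_affine_invariance(self, seed, a, b):
        rng = np.random.default_rng(seed)
        m = random_interaction_matrix(rng, 6)
        x = rng.normal(size=6)
        assert mn.moran_i(m, a * x + b) == pytest.approx(mn.moran_i(m, x), abs=1e-9)

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(5)
        m = random_interaction_matrix(rng, 7)
        x = rng.normal(size=7)
        m3 = mn.InteractionMatrix(m.ids, m.counts * 3)
        assert mn.moran_i(m3, x) == pytest.approx(mn.moran_i(m, x), abs=1e-12)

    def test_constant_attribute_rejected(self):
        m = mn.InteractionMatrix(["a", "b"], np.array([[0, 1], [1, 0]]))
        with pytest.raises(mn.DegenerateAttributeError):
            mn.moran_i(m, np.array([2.0, 2.0]))

    def test_zero_network_rejected(self):
        m = mn.InteractionMatrix(["a", "b"], np.zeros((2, 2), dtype=int))
        with pytest.raises(mn.DegenerateNetworkError):
            mn.moran_i(m, np.array([1.0, 2.0]))


class TestMoranTest:
    def test_exact_enumeration_agreement(self):
        """With all n!-1 permutations, the engine's p equals an
        independent exhaustive-enumeration oracle (n = 5)."""
        rng = np.random.default_rng(2)
        m = random_interaction_matrix(rng, 5)
        x = rng.normal(size=5)
        res = mn.moran_test(m, x, n_perm="exact", seed=0)
        assert res.n_perm == math.factorial(5) - 1
        w = m.counts.astype(float)
        obs = brute_force_moran(w, x)
        null = [
            brute_force_moran(w, x[list(p)])
            for p in itertools.permutations(range(5))
            if p != tuple(range(5))
        ]
        null = np.array(null)
        pg = (1 + np.sum(null >= obs)) / (1 + len(null))
        pl = (1 + np.sum(null <= obs)) / (1 + len(null))
        assert res.p_value == pytest.approx(min(1.0, 2 * min(pg, pl)), abs=1e-15)

    def test_null_mean_by_enumeration_n4(self):
        """The full-permutation mean of Moran's I is exactly -1/(n-1)."""
        rng = np.random.default_rng(3)
        m = random_interaction_matrix(rng, 4, density=0.8)
        x = np.array([1.0, 4.0, 2.0, 8.0])
        vals = [
            brute_force_moran(m.counts.astype(float), x[list(p)])
            for p in itertools.permutations(range(4))
        ]
        assert np.mean(vals) == pytest.approx(-1 / 3, abs=1e-12)
        # and the engine's sampled null mean is close
        res = mn.moran_test(m, x, n_perm=2000, seed=0)
        assert res.null_sample.mean() == pytest.approx(-1 / 3, abs=0.05)

    def test_planted_assortativity_detected(self):
        """Strong age homophily in the generator gives I > 0, significant."""
        cfg = mn.GeneratorConfig(beta_age_homophily=4.0)
        attrs, ago, _, _ = mn.generate_dataset(cfg, seed=5)
        res = mn.moran_test(ago, attrs["age"].to_numpy(), "age", n_perm=199, seed=1)
        assert res.statistic > 0 and res.p_value < 0.05


class TestSubgroupTests:
    def test_pooled_equals_full_matrix_test(self, small_troop):
        _, attrs, ago, _, _ = small_troop
        results = mn.subgroup_tests(ago, attrs, "age", n_perm=99, seed=4)
        pooled = [r for r in results if r.subgroup == "all"][0]
        from macanet._seeding import derive_seed

        direct = mn.moran_test(
            ago, attrs["age"].to_numpy(), "age", 99,
            derive_seed(4, "homophily|age|moran_i|all"),
        )
        assert pooled.statistic == pytest.approx(direct.statistic)
        assert pooled.p_value == pytest.approx(direct.p_value)

    def test_three_rows_per_attribute(self, small_troop):
        _, attrs, ago, _, _ = small_troop
        results = mn.subgroup_tests(ago, attrs, "age", n_perm=19, seed=0)
        assert [r.subgroup for r in results] == ["all", "F_only", "M_only"]

    def test_identical_subnetworks_symmetric(self):
        """Mirror-image female and male blocks give equal subgroup stats."""
        block = np.array([[0, 3, 1], [2, 0, 2], [1, 1, 0]])
        counts = np.zeros((6, 6), dtype=int)
        counts[:3, :3] = block
        counts[3:, 3:] = block
        ids = [f"f{k}" for k in range(3)] + [f"m{k}" for k in range(3)]
        m = mn.InteractionMatrix(ids, counts)
        attrs = _attrs_from(
            ids, gender=["F"] * 3 + ["M"] * 3, age=[3.0, 7, 11, 3, 7, 11]
        )
        results = mn.subgroup_tests(m, attrs, "age", n_perm=49, seed=9)
        by = {r.subgroup: r for r in results}
        assert by["F_only"].statistic == pytest.approx(by["M_only"].statistic)

    def test_degenerate_subgroup_reported_not_raised(self):
        ids = ["f1", "f2", "f3", "f4", "m1", "m2"]
        counts = np.zeros((6, 6), dtype=int)
        counts[0, 1] = counts[1, 0] = 2
        counts[2, 3] = 1
        counts[4, 5] = counts[5, 4] = 1
        m = mn.InteractionMatrix(ids, counts)
        attrs = _attrs_from(ids, gender=["F"] * 4 + ["M"] * 2, age=[1.0, 2, 3, 4, 5, 6])
        results = mn.subgroup_tests(m, attrs, "age", n_perm=19, seed=0)
        by = {r.subgroup: r for r in results}
        assert math.isnan(by["M_only"].statistic)
        assert by["M_only"].note != ""
        assert not math.isnan(by["all"].statistic)
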