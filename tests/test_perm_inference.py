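import math

import numpy as np
import pandas as pd
import pytest

import macanet as mn
from macanet.metrics import MetricVector


def _attrs(n, rng=None, hierarchy=True):
    rng = rng or np.random.default_rng(0)
    ids = [f"i{k}" for k in range(n)]
    df = pd.DataFrame(
        {
            "gender": rng.choice(["F", "M"], n),
            "age": rng.integers(1, 26, n).astype(float),
            "matriline": rng.integers(1, 5, n).astype(float),
            "hierarchy": rng.permutation(n) + 1.0 if hierarchy else np.nan,
        },
        index=pd.Index(ids, name="id"),
    )
    return mn.AttributeTable(df)


class TestPermuteNodeLabels:
    def test_deterministic_under_seed(self):
        attrs = _attrs(6)
        a = mn.permute_node_labels(attrs, np.random.default_rng(5))
        b = mn.permute_node_labels(attrs, np.random.default_rng(5))
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_marginals_preserved(self):
        attrs = _attrs(10)
        perm = mn.permute_node_labels(attrs, np.random.default_rng(1))
        assert sorted(perm["age"]) == sorted(attrs["age"])
        assert sorted(perm["gender"]) == sorted(attrs["gender"])
        assert perm.ids == attrs.ids  # ids stay put; rows move

    def test_rows_travel_jointly(self):
        attrs = _attrs(8)
        perm = mn.permute_node_labels(attrs, np.random.default_rng(2))
        original_rows = {tuple(r) for r in attrs.data.itertuples(index=False)}
        permuted_rows = {tuple(r) for r in perm.data.itertuples(index=False)}
        assert original_rows == permuted_rows

    def test_uniform_over_small_group(self):
        """Each of the 3! = 6 permutations appears ~1/6 of the time."""
        attrs = _attrs(3)
        ages = attrs["age"].to_numpy()
        rng = np.random.default_rng(99)
        counts = {}
        n_draw = 10_000
        for _ in range(n_draw):
            drawn = tuple(mn.permute_node_labels(attrs, rng)["age"])
            counts[drawn] = counts.get(drawn, 0) + 1
        assert len(counts) == 6
        sigma = np.sqrt(n_draw * (1 / 6) * (5 / 6))
        for c in counts.values():
            assert abs(c - n_draw / 6) < 3.5 * sigma


class TestPermutationPvalue:
    def test_hand_count(self):
        assert mn.permutation_pvalue(10, np.arange(1, 10), "greater") == pytest.approx(0.1)

    def test_ties_count_against_rejection(self):
        assert mn.permutation_pvalue(5.0, np.full(9, 5.0), "greater") == 1.0

    def test_bounds(self):
        null = np.arange(1, 10)
        assert mn.permutation_pvalue(0, null, "greater") == 1.0
        assert mn.permutation_pvalue(0, null, "less") == pytest.approx(0.1)

    def test_two_sided_caps_at_one(self):
        assert mn.permutation_pvalue(5.0, np.full(5, 5.0), "two_sided") == 1.0

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            mn.permutation_pvalue(1.0, np.array([]))

    def test_never_exactly_zero(self):
        p = mn.permutation_pvalue(100.0, np.zeros(99), "greater")
        assert p == pytest.approx(1 / 100) and p > 0


class TestFitAttributeModel:
    def test_estimates_equal_statsmodels_ols(self):
        """Dual route: the permutation engine's point estimates are plain OLS."""
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        attrs = _attrs(40, rng)
        y = rng.normal(size=40)
        mv = MetricVector("degree", attrs.ids, y)
        for kind in ("main_effects", "gender_interaction"):
            t = mn.fit_attribute_model(mv, attrs, kind, n_perm=10, n_boot=0, seed=0)
            from macanet.perm_inference import _design_matrix

            X, _, keep = _design_matrix(attrs, kind)
            ref = sm.OLS(y[keep], X).fit()
            np.testing.assert_allclose(t.estimates, ref.params, atol=1e-10)

    def test_planted_coefficient_recovered(self):
        rng = np.random.default_rng(8)
        attrs = _attrs(40, rng)
        y = 2.0 * attrs["age"].to_numpy() + rng.normal(0, 1e-8, 40)
        mv = MetricVector("degree", attrs.ids, y)
        t = mn.fit_attribute_model(mv, attrs, "main_effects", n_perm=499, n_boot=50, seed=1)
        assert t.estimate("Age") == pytest.approx(2.0, abs=1e-6)
        # two-sided floor: 2 * (1 / (n_perm + 1))
        assert t.p_value("Age") == pytest.approx(2 / 500, abs=1e-12)
        assert t.significant[t.terms.index("Age")]

    def test_zero_metric_no_signal(self):
        attrs = _attrs(30)
        mv = MetricVector("degree", attrs.ids, np.zeros(30))
        t = mn.fit_attribute_model(mv, attrs, n_perm=99, n_boot=0, seed=0)
        np.testing.assert_allclose(t.estimates, 0.0, atol=1e-12)
        assert not t.significant.any()

    def test_missing_matriline_rows_dropped(self):
        attrs = _attrs(30)
        df = attrs.data.copy()
        df.iloc[:4, df.columns.get_loc("matriline")] = np.nan
        attrs = mn.AttributeTable(df)
        mv = MetricVector("degree", attrs.ids, np.arange(30.0))
        t = mn.fit_attribute_model(mv, attrs, n_perm=9, n_boot=0, seed=0)
        assert t.n_dropped == 4 and t.n_used == 26

    def test_rank_deficient_design_rejected(self):
        attrs = _attrs(20)
        df = attrs.data.copy()
        df["age"] = 7.0  # constant -> collinear with intercept
        with pytest.raises(mn.DesignError, match="Age|rank"):
            mn.fit_attribute_model(
                MetricVector("degree", attrs.ids, np.arange(20.0)),
                mn.AttributeTable(df),
                n_perm=9,
                n_boot=0,
            )

    def test_too_few_rows_rejected(self):
        attrs = _attrs(6)
        with pytest.raises(mn.DesignError, match="rows"):
            mn.fit_attribute_model(
                MetricVector("degree", attrs.ids, np.arange(6.0)),
                attrs,
                n_perm=9,
                n_boot=0,
            )

    def test_effect_floor_suppression(self):
        """A term with a tiny but highly significant estimate is suppressed
        by the 0.009 floor and flagged as such."""
        rng = np.random.default_rng(5)
        attrs = _attrs(40, rng)
        y = 0.005 * attrs["age"].to_numpy() + rng.normal(0, 1e-9, 40)
        mv = MetricVector("eigenvector", attrs.ids, y)
        t = mn.fit_attribute_model(mv, attrs, n_perm=199, n_boot=0, seed=2)
        i = t.terms.index("Age")
        assert t.p_values[i] < 0.05
        assert not t.significant[i]
        assert t.floor_suppressed[i]

    def test_exact_mode_enumerates_all_permutations(self):
        """n_perm='exact' uses every non-identity permutation, and two
        exact runs agree regardless of seed (no sampling left)."""
        rng = np.random.default_rng(12)
        attrs = _attrs(7, rng)
        mv = MetricVector("degree", attrs.ids, rng.normal(size=7))
        t1 = mn.fit_attribute_model(mv, attrs, n_perm="exact", n_boot=0, seed=1)
        t2 = mn.fit_attribute_model(mv, attrs, n_perm="exact", n_boot=0, seed=999)
        assert t1.n_perm == math.factorial(7) - 1
        np.testing.assert_array_equal(t1.p_values, t2.p_values)


class TestMetricAttributeReport:
    def test_twenty_tables_and_determinism(self, small_troop):
        _, attrs, ago, gro, _ = small_troop
        attrs = attrs.with_hierarchy(mn.dominance_from_matrix(ago).rank_series)
        kwargs = dict(n_perm=50, n_boot=20, seed=7)
        rep1 = mn.metric_attribute_report(ago, gro, attrs, **kwargs)
        rep2 = mn.metric_attribute_report(ago, gro, attrs, **kwargs)
        assert len(rep1) == 20
        assert {k[0] for k in rep1} == {"agonistic", "allogrooming"}
        for key in rep1:
            a, b = rep1[key].to_frame(), rep2[key].to_frame()
            assert a.to_csv() == b.to_csv()  # byte-identical

    def test_planted_female_grooming_effect(self, small_troop):
        """Generator plants 'females groom more'; the grooming degree model
        must show a positive, significant gender estimate."""
        _, attrs, ago, gro, _ = small_troop
        attrs = attrs.with_hierarchy(mn.dominance_from_matrix(ago).rank_series)
        mv = mn.strength(gro, "total")
        t = mn.fit_attribute_model(mv, attrs, n_perm=199, n_boot=0, seed=3)
        i = t.terms.index("Gender")
        assert t.estimates[i] > 0
        assert t.p_values[i] < 0.05
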