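"""Hypergeometric enrichment, FCOP normalization and concordance."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import omvscreen as o


def exact_tail(N, K, n, k):
    """Big-integer enumeration oracle for P(X >= k)."""
    num = sum(comb(K, j) * comb(N - K, n - j)
              for j in range(k, min(K, n) + 1))
    return Fraction(num, comb(N, n))


class TestHypergeomUpperTail:
    def test_whole_support_is_exactly_one(self):
        assert o.hypergeom_upper_tail(100, 30, 10, 0) == 1.0

    def test_hand_enumerated_example(self):
        # C(4,3)C(6,2) + C(4,4)C(6,1) over C(10,5) = 66/252
        assert o.hypergeom_upper_tail(10, 4, 5, 3) == \
            pytest.approx(66 / 252, rel=1e-12)

    def test_exhaustive_small_universe(self):
        for N in range(0, 26):
            for K in range(0, N + 1):
                for n in range(0, N + 1):
                    ks = np.arange(0, min(K, n) + 1)
                    got = np.atleast_1d(o.hypergeom_upper_tail(N, K, n, ks))
                    want = [float(exact_tail(N, K, n, int(k))) for k in ks]
                    np.testing.assert_allclose(got, want, rtol=1e-12)

    @given(st.integers(1, 80), st.data())
    def test_duality_in_draws_and_successes(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(0, min(K, n)))
        assert o.hypergeom_upper_tail(N, K, n, k) == \
            pytest.approx(o.hypergeom_upper_tail(N, n, K, k), rel=1e-10)

    @pytest.mark.parametrize("args", [
        (10, 11, 5, 0), (10, 4, 11, 0), (10, 4, 5, 5), (10, 4, 5, -1),
    ])
    def test_bounds_violations_rejected(self, args):
        with pytest.raises(ValueError):
            o.hypergeom_upper_tail(*args)


def annotation(categories, universe):
    return o.AnnotationSet(categories={k: set(v) for k, v in
                                       categories.items()},
                           universe=set(universe))


class TestEnrichCategories:
    UNIVERSE = [f"g{i}" for i in range(100)]

    def test_disjoint_category_never_flagged(self):
        ann = annotation({"c1": self.UNIVERSE[:10]}, self.UNIVERSE)
        res = o.enrich_categories(set(self.UNIVERSE[50:60]), ann)
        row = res.iloc[0]
        assert row["k"] == 0 and row["p"] == 1.0 and not row["enriched"]

    def test_significant_equals_universe(self):
        ann = annotation({"c1": self.UNIVERSE[:10]}, self.UNIVERSE)
        res = o.enrich_categories(set(self.UNIVERSE), ann)
        row = res.iloc[0]
        assert row["k"] == row["K"] and row["p"] == pytest.approx(1.0)

    def test_empty_significant_set_yields_empty_table(self):
        ann = annotation({"c1": self.UNIVERSE[:10]}, self.UNIVERSE)
        assert o.enrich_categories(set(), ann).empty

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(11)
        sig = set(rng.choice(self.UNIVERSE, 20, replace=False))
        cats = {"a": set(rng.choice(self.UNIVERSE, 15, replace=False)),
                "b": set(rng.choice(self.UNIVERSE, 30, replace=False))}
        res1 = o.enrich_categories(sig, annotation(cats, self.UNIVERSE))
        relabel = {g: f"x{g}" for g in self.UNIVERSE}
        res2 = o.enrich_categories(
            {relabel[g] for g in sig},
            annotation({c: {relabel[g] for g in v} for c, v in cats.items()},
                       {relabel[g] for g in self.UNIVERSE}))
        np.testing.assert_allclose(res1["p"], res2["p"], rtol=1e-14)

    def test_jaccard_redundancy_filter(self):
        sig = set(self.UNIVERSE[:10])
        cats = {"best": set(self.UNIVERSE[:12]),
                "copy": set(self.UNIVERSE[:12]) | {self.UNIVERSE[20]},
                "other": set(self.UNIVERSE[40:55])}
        res = o.enrich_categories(sig, annotation(cats, self.UNIVERSE),
                                  max_jaccard=0.8)
        assert "copy" not in set(res["category_id"])
        assert {"best", "other"} <= set(res["category_id"])


class TestOverlapSignificance:
    def test_disjoint_sets(self):
        universe = {f"g{i}" for i in range(50)}
        res = o.overlap_significance({"g0", "g1"}, {"g10", "g11"}, universe)
        assert res.k == 0 and res.p == 1.0

    def test_nested_sets_match_enumeration(self):
        universe = [f"g{i}" for i in range(40)]
        set_a = set(universe[:15])
        set_b = set(universe[:6])  # subset of A -> k = n
        res = o.overlap_significance(set_a, set_b, set(universe))
        assert res.k == 6
        assert res.p == pytest.approx(float(exact_tail(40, 15, 6, 6)),
                                      rel=1e-12)

    def test_screen_scale_overlap_matches_enumeration(self):
        # a hit list of 171 in a 3,800-strain universe vs a 20-gene panel
        p = o.overlap_significance(
            {f"g{i}" for i in range(171)},
            {f"g{i}" for i in range(160, 180)},
            {f"g{i}" for i in range(3800)}).p
        assert p == pytest.approx(float(exact_tail(3800, 171, 20, 11)),
                                  rel=1e-10)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            o.overlap_significance(set(), set(), set())


def fcop_frame(rows):
    return pd.DataFrame(rows, columns=["strain", "replicate", "fm464", "cfu"])


class TestFcopVesiculation:
    WT = [("WT", r, 1000.0, 1e9) for r in (1, 2, 3)]

    def test_wild_type_is_exactly_one(self):
        vals = o.fcop_vesiculation(fcop_frame(self.WT), "WT")
        assert vals.set_index("strain").loc["WT", "fcop_value"] == 1.0

    def test_doubled_ratio_gives_two(self):
        rows = self.WT + [("mut", 1, 2000.0, 1e9), ("mut", 2, 2000.0, 1e9)]
        vals = o.fcop_vesiculation(fcop_frame(rows), "WT")
        assert vals.set_index("strain").loc["mut", "fcop_value"] == \
            pytest.approx(2.0)

    def test_hand_computed_example(self):
        # strain ratios 2.0e-6 and 2.2e-6 against a WT mean ratio of 1e-6
        rows = self.WT + [("mut", 1, 2000.0, 1e9), ("mut", 2, 2200.0, 1e9)]
        vals = o.fcop_vesiculation(fcop_frame(rows), "WT")
        assert vals.set_index("strain").loc["mut", "fcop_value"] == \
            pytest.approx(2.1)

    def test_missing_wild_type_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            o.fcop_vesiculation(fcop_frame([("mut", 1, 1.0, 1e9)] * 1), "WT")

    def test_zero_cfu_names_the_row(self):
        rows = self.WT + [("mut", 2, 1000.0, 0.0)]
        with pytest.raises(ValueError, match="'mut' replicate 2"):
            o.fcop_vesiculation(fcop_frame(rows), "WT")

    @given(st.floats(min_value=0.1, max_value=100))
    def test_fluorescence_rescaling_invariance(self, c):
        rows = self.WT + [("mut", 1, 1500.0, 2e9), ("mut", 2, 900.0, 1e9),
                          ("mut", 3, 1100.0, 1e9)]
        df = fcop_frame(rows)
        base = o.fcop_vesiculation(df, "WT")
        scaled = o.fcop_vesiculation(df.assign(fm464=df["fm464"] * c), "WT")
        np.testing.assert_allclose(scaled["fcop_value"], base["fcop_value"],
                                   rtol=1e-12)


class TestMethodConcordance:
    def test_perfect_agreement(self):
        htp = pd.Series({"a": -0.5, "b": 0.2, "c": 0.7, "d": -0.1})
        res = o.method_concordance(htp, 10.0 ** htp)
        assert res.correlation == pytest.approx(1.0)
        assert res.sign_agree == res.sign_total == 4

    def test_perfect_anticorrelation(self):
        htp = pd.Series({"a": -1.0, "b": 0.0, "c": 1.0})
        fcop = pd.Series({"a": 10.0, "b": 1.0, "c": 0.1})
        res = o.method_concordance(htp, fcop)
        assert res.correlation == pytest.approx(-1.0)
        # the exact-zero pair agrees with anything; the others disagree
        assert res.sign_agree == 1

    def test_anti_signed_pairs_have_zero_agreement(self):
        htp = pd.Series({"a": -1.0, "b": 0.5, "c": 1.0})
        fcop = pd.Series({"a": 10.0, "b": 0.5, "c": 0.2})
        assert o.method_concordance(htp, fcop).sign_agree == 0

    def test_affine_invariance_of_correlation(self):
        rng = np.random.default_rng(2)
        htp = pd.Series(rng.normal(0, 0.3, 12),
                        index=[f"s{i}" for i in range(12)])
        fcop = pd.Series(10.0 ** (htp * 0.8 + rng.normal(0, 0.1, 12)),
                         index=htp.index)
        base = o.method_concordance(htp, fcop)
        shifted = o.method_concordance(htp * 3.0 + 1.0, fcop)
        assert shifted.correlation == pytest.approx(base.correlation,
                                                    rel=1e-9)

    def test_unpaired_strains_dropped(self):
        htp = pd.Series({"a": 0.1, "b": 0.2, "c": -0.3, "zzz": 1.0})
        fcop = pd.Series({"a": 1.2, "b": 1.5, "c": 0.6, "yyy": 2.0})
        assert o.method_concordance(htp, fcop).n_pairs == 3

    def test_too_few_pairs_rejected(self):
        htp = pd.Series({"a": 0.1, "b": 0.2})
        with pytest.raises(ValueError, match="at least 3"):
            o.method_concordance(htp, pd.Series({"a": 1.0, "b": 1.0}))

    def test_spearman_mode(self):
        htp = pd.Series({"a": -0.5, "b": 0.2, "c": 0.7, "d": -0.1})
        res = o.method_concordance(htp, 10.0 ** htp, method="spearman")
        assert res.correlation == pytest.approx(1.0)
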