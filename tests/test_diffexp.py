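import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lncnet import diffexp
from lncnet.diffexp import bh_adjust, call_de, fold_change, nb_test, venn_membership
from lncnet.types import COMPARISON_LABELS

from conftest import make_design, make_expression


class TestFoldChange:
    def test_doubling(self):
        expr = make_expression({"f": [4.0] * 3 + [2.0] * 9})  # W6=4, others 2
        res = fold_change(expr, ("W6", "W14"), pseudocount=0.0)
        assert res.loc["f", "fold_change"] == pytest.approx(2.0)
        assert res.loc["f", "log2fc"] == pytest.approx(1.0)

    def test_equal_means_give_unity(self):
        expr = make_expression({"f": [3.0] * 12})
        res = fold_change(expr, "W14vW6", pseudocount=0.0)
        assert res.loc["f", "fold_change"] == pytest.approx(1.0)

    def test_zero_vs_zero_forced_to_unity_by_pseudocount(self):
        expr = make_expression({"f": [0.0] * 12})
        res = fold_change(expr, "W14vW6", pseudocount=0.01)
        assert res.loc["f", "fold_change"] == pytest.approx(1.0)
        assert res.loc["f", "log2fc"] == pytest.approx(0.0)


class TestNbTest:
    def test_identical_groups_give_p_one(self):
        expr = make_expression(
            {"f": [1.0] * 12}, counts={"f": [7, 9, 11] * 4}
        )
        p = nb_test(expr, "W14vW6")
        assert p["f"] == pytest.approx(1.0)

    def test_huge_separation_gives_tiny_p(self):
        # group means 5 vs 500: the Wald statistic exceeds 10
        expr = make_expression(
            {"f": [1.0] * 12},
            counts={"f": [5, 5, 5] + [500, 500, 500] + [1] * 6},
        )
        p = nb_test(expr, ("W6", "W14"))
        assert p["f"] < 1e-6

    def test_null_calibration(self):
        """Under the null the empirical type-I rate at alpha=0.05 is nominal."""
        rng = np.random.default_rng(12345)
        n = 2000
        disp = 0.1
        r = 1.0 / disp
        mus = rng.lognormal(np.log(20.0), 1.0, size=n)
        counts = rng.negative_binomial(r, r / (r + mus[:, None]), size=(n, 12))
        design = make_design()
        table = pd.DataFrame(counts, index=[f"f{i}" for i in range(n)], columns=list(design))
        p = nb_test(table, "W14vW6", design=design)
        frac = float((p < 0.05).mean())
        assert 0.035 <= frac <= 0.065

    def test_non_integer_counts_rejected(self):
        design = make_design()
        table = pd.DataFrame([[1.5] * 12], index=["f"], columns=list(design))
        with pytest.raises(ValueError, match="integer"):
            nb_test(table, "W14vW6", design=design)


def _bh_reference(p):
    """Independent step-up: q_(i) = min_{j>=i} p_(j) * n / j."""
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = np.inf
    for rank in range(n - 1, -1, -1):
        running = min(running, p[order[rank]] * n / (rank + 1))
        q[order[rank]] = min(running, 1.0)
    return q


class TestBhAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_identity(self):
        np.testing.assert_allclose(bh_adjust([0.04]), [0.04])

    def test_matches_reference_step_up(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.random(int(rng.integers(1, 60)))
            np.testing.assert_allclose(bh_adjust(p), _bh_reference(p), atol=1e-12)

    def test_bounds_property(self):
        rng = np.random.default_rng(6)
        p = rng.random(500)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(st.floats(0, 1), min_size=2, max_size=20),
        st.data(),
    )
    def test_monotone_in_each_p(self, ps, data):
        """Raising one p-value never lowers its own q-value."""
        i = data.draw(st.integers(0, len(ps) - 1))
        bumped = list(ps)
        bumped[i] = min(1.0, bumped[i] + data.draw(st.floats(0.0, 1.0)))
        q0 = bh_adjust(ps)
        q1 = bh_adjust(bumped)
        assert q1[i] >= q0[i] - 1e-12

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCallDe:
    @pytest.mark.parametrize(
        "fc, q, is_de, cerna",
        [
            (1.7, 0.049, True, False),  # FC boundary inclusive, q strict
            (1.69, 0.001, False, False),
            (2.0, 0.049, True, True),
            (1 / 1.7, 0.049, True, False),  # direction-symmetric
            (1.7, 0.05, False, False),  # q boundary strict
        ],
    )
    def test_thresholds(self, fc, q, is_de, cerna):
        df = pd.DataFrame(
            {"fold_change": [fc], "log2fc": [np.log2(fc)], "q": [q]}, index=["f"]
        )
        out = call_de(df)
        assert bool(out.loc["f", "is_de"]) is is_de
        assert bool(out.loc["f", "is_cerna_grade"]) is cerna


class TestVenn:
    def test_feature_in_all_six(self):
        sets = {g: {"f"} for g in COMPARISON_LABELS}
        _table, regions = venn_membership(sets)
        assert regions[frozenset(COMPARISON_LABELS)] == 1

    def test_disjoint_sets_have_no_multi_regions(self):
        sets = {g: {f"f{i}"} for i, g in enumerate(COMPARISON_LABELS)}
        _table, regions = venn_membership(sets)
        assert all(len(k) == 1 for k in regions)

    def test_matches_exhaustive_region_enumeration(self):
        rng = np.random.default_rng(9)
        universe = [f"f{i}" for i in range(100)]
        sets = {
            g: set(rng.choice(universe, size=20, replace=False)) for g in COMPARISON_LABELS
        }
        _table, regions = venn_membership(sets)
        # brute force over all 2^6 regions
        for k in range(1, 7):
            for combo in itertools.combinations(COMPARISON_LABELS, k):
                inside = set(combo)
                members = set(universe)
                for g in COMPARISON_LABELS:
                    members &= sets[g] if g in inside else (set(universe) - sets[g])
                expected = len(members)
                assert regions.get(frozenset(combo), 0) == expected

    def test_unknown_group_rejected(self):
        sets = {g: set() for g in COMPARISON_LABELS}
        sets["W99vW6"] = set()
        with pytest.raises(KeyError, match="W99vW6"):
            venn_membership(sets)
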