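"""Ordering constraints, the directionality gate, and the R^2 screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ebscreen.ordering import (
    OrderingConstraint,
    apply_gate,
    check_ordering,
    constraint_preset,
    derive_condition_order,
    parse_constraint,
    univariate_r2,
)
from ebscreen.simulate import simulate_phenotype

MU_ORDER = ["OV90", "OVCAR4", "OVCAR3", "OVCAR5", "OVCA432"]


def pairwise_ok(values, relations):
    """Oracle: direct pairwise comparison with exact arithmetic."""
    for (a, b), rel in zip(zip(values, values[1:]), relations):
        if rel == "<=" and not a <= b:
            return False
        if rel == ">=" and not a >= b:
            return False
        if rel == "=" and a != b:
            return False
    return True


class TestParse:
    def test_simple_chain(self):
        c = parse_constraint("A<=B<=C")
        assert c.labels == ("A", "B", "C")
        assert c.relations == ("<=", "<=")
        assert c.to_text() == "A<=B<=C"

    def test_final_descending_relation(self):
        c = parse_constraint("OV90<=OVCAR4<=OVCAR3<=OVCAR5>=OVCA432")
        assert c.relations == ("<=", "<=", "<=", ">=")

    def test_mixed_relations(self):
        c = parse_constraint("A<=B>=C=D")
        assert c.relations == ("<=", ">=", "=")

    def test_malformed_and_unknown_labels(self):
        with pytest.raises(ValueError):
            parse_constraint("A<=")
        with pytest.raises(ValueError):
            parse_constraint("A<=B", known_labels=["A", "C"])

    def test_presets_round_trip(self):
        c1 = constraint_preset("c1_main")
        assert c1.labels == tuple(MU_ORDER)
        assert c1.relations == ("<=",) * 4
        c2s = constraint_preset("c2_supp")
        assert c2s.relations == ("=", "=", "<=", ">=") and c2s.strict


class TestGateOracle:
    def test_monotone_candidate_passes_strict_ascending_chain(self, candidate_means):
        c1 = constraint_preset("c1_main")
        ok, rec = check_ordering(candidate_means.loc["TGFA"], c1)
        assert ok and rec.first_violation is None

    def test_gdnf_fails_both_criteria(self, candidate_means):
        c1 = constraint_preset("c1_main")
        c2 = constraint_preset("c2_main")
        ok1, rec1 = check_ordering(candidate_means.loc["GDNF"], c1)
        ok2, rec2 = check_ordering(candidate_means.loc["GDNF"], c2)
        assert not ok1 and not ok2
        assert rec1.first_violation == 2  # 0.16 > 0.00 breaks the ascent
        assert rec2.first_violation == 2

    def test_gate_retains_exactly_the_strictly_monotone_rows(self, candidate_means):
        c1 = constraint_preset("c1_main")
        kept, report = apply_gate(list(candidate_means.index), candidate_means, [c1])
        # independent oracle: plain pairwise comparison per row
        expect = sorted(
            g
            for g in candidate_means.index
            if pairwise_ok(list(candidate_means.loc[g]), ["<="] * 4)
        )
        assert sorted(kept) == expect == ["AMH", "EPGN", "LIF", "TGFA"]
        assert report["passed"].sum() == 4

    def test_disjunction_keeps_gene_passing_second_constraint_only(self):
        means = pd.DataFrame({"A": [1.0], "B": [5.0], "C": [2.0]}, index=["g"])
        c_up = parse_constraint("A<=B<=C")
        c_peak = parse_constraint("A<=B>=C")
        kept_any, _ = apply_gate(["g"], means, [c_up, c_peak], mode="any")
        kept_all, _ = apply_gate(["g"], means, [c_up, c_peak], mode="all")
        assert kept_any == ["g"] and kept_all == []

    def test_all_equal_vector_passes_equality_chain(self):
        ok, _ = check_ordering(
            pd.Series({"A": 4.0, "B": 4.0, "C": 4.0}), parse_constraint("A=B=C")
        )
        assert ok

    def test_empty_inputs(self, candidate_means):
        c1 = constraint_preset("c1_main")
        kept, _ = apply_gate([], candidate_means, [c1])
        assert kept == []
        with pytest.raises(ValueError):
            apply_gate(["AMH"], candidate_means, [])


class TestGateProperties:
    @given(
        st.lists(
            st.floats(min_value=0, max_value=1e4, allow_nan=False),
            min_size=3,
            max_size=6,
        ),
        st.data(),
    )
    def test_reversal_symmetry(self, values, data):
        labels = [f"C{i}" for i in range(len(values))]
        relations = tuple(
            data.draw(st.sampled_from(["<=", ">=", "="]))
            for _ in range(len(values) - 1)
        )
        c = OrderingConstraint(labels=tuple(labels), relations=relations)
        mu = pd.Series(dict(zip(labels, values)))
        ok_fwd, _ = check_ordering(mu, c)
        ok_rev, _ = check_ordering(mu, c.reversed())
        assert ok_fwd == ok_rev

    @given(
        st.lists(
            st.floats(min_value=0, max_value=100, allow_nan=False),
            min_size=3,
            max_size=5,
        ),
        st.floats(min_value=0, max_value=0.5),
        st.floats(min_value=0, max_value=0.5),
    )
    def test_tolerance_monotonicity(self, values, t1, t2):
        lo, hi = sorted([t1, t2])
        labels = [f"C{i}" for i in range(len(values))]
        mu = pd.Series(dict(zip(labels, values)))
        base = parse_constraint("<=".join(labels), rel_tol=lo)
        loose = parse_constraint("<=".join(labels), rel_tol=hi)
        if check_ordering(mu, base)[0]:
            assert check_ordering(mu, loose)[0]

    def test_gate_output_is_subset_of_input(self, candidate_means):
        c2 = constraint_preset("c2_main")
        kept, _ = apply_gate(["LIF", "GDNF"], candidate_means, [c2])
        assert set(kept) <= {"LIF", "GDNF"}

    def test_soft_tolerance_admits_near_monotone_rows(self, candidate_means):
        """A 5% relative tolerance lets shallow dips through the ascent."""
        strict = constraint_preset("c1_main")
        soft = constraint_preset("c1_main", rel_tol=0.05)
        kept_strict, _ = apply_gate(
            list(candidate_means.index), candidate_means, [strict]
        )
        kept_soft, _ = apply_gate(list(candidate_means.index), candidate_means, [soft])
        assert set(kept_strict) <= set(kept_soft)


class TestConditionOrder:
    def test_noiseless_recovery_of_requested_order(self):
        pheno = simulate_phenotype(["A", "B", "C"], noise_sd=0.0)
        assert derive_condition_order(pheno, "CD68") == ["A", "B", "C"]

    def test_macrophage_ranking_recovered(self):
        order = ["OV90", "OVCAR4", "OVCAR3", "OVCA432", "OVCAR5"]
        pheno = simulate_phenotype(order, noise_sd=0.0, n_donors=3)
        assert derive_condition_order(pheno, "CD68") == order

    def test_tied_conditions_break_lexicographically_with_warning(self):
        pheno = pd.DataFrame(
            {
                "donor": ["d1"] * 3,
                "condition": ["b", "a", "c"],
                "CD68": [5.0, 5.0, 1.0],
            }
        )
        with pytest.warns(UserWarning, match="tied"):
            assert derive_condition_order(pheno, "CD68") == ["c", "a", "b"]

    def test_single_condition_and_missing_marker(self):
        pheno = pd.DataFrame({"donor": ["d1"], "condition": ["A"], "CD68": [3.0]})
        assert derive_condition_order(pheno, "CD68") == ["A"]
        with pytest.raises(KeyError):
            derive_condition_order(pheno, "CD163")

    def test_invariance_to_donor_permutation_and_scaling(self):
        pheno = simulate_phenotype(["A", "B", "C"], noise_sd=2.0, n_donors=4, seed=9)
        base = derive_condition_order(pheno, "CD68")
        shuffled = pheno.sample(frac=1.0, random_state=1)
        scaled = pheno.assign(CD68=pheno["CD68"] * 7.5)
        assert derive_condition_order(shuffled, "CD68") == base
        assert derive_condition_order(scaled, "CD68") == base


class TestUnivariateR2:
    def test_collinear_is_one(self):
        r = univariate_r2([1, 2, 3, 4], [2, 4, 6, 8])
        assert np.isclose(r.r2, 1.0) and r.direction == 1

    def test_orthogonal_is_zero(self):
        r = univariate_r2([-1, 0, 1], [1, -2, 1])
        assert np.isclose(r.r2, 0.0)

    def test_five_point_toy_matches_sum_formulas(self):
        x = [1.0, 2.0, 4.0, 5.0, 9.0]
        y = [3.0, 1.0, 6.0, 8.0, 13.0]
        n = len(x)
        sx, sy = sum(x), sum(y)
        sxy = sum(a * b for a, b in zip(x, y))
        sxx = sum(a * a for a in x)
        syy = sum(b * b for b in y)
        expect = (n * sxy - sx * sy) ** 2 / ((n * sxx - sx**2) * (n * syy - sy**2))
        got = univariate_r2(x, y)
        assert np.isclose(got.r2, expect, atol=1e-12)
        assert got.direction == 1

    def test_constant_feature_is_undefined_not_zero(self):
        r = univariate_r2([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert np.isnan(r.r2) and not r.defined

    def test_constant_response_raises(self):
        with pytest.raises(ValueError):
            univariate_r2([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
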