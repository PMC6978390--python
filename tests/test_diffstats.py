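"""Normalization and hypothesis-test statistics for perturbation readouts."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from creplexus.diffstats import (
    AlleleEnrichment,
    ExpressionMeasurement,
    allele_log2fc,
    benjamini_hochberg,
    efficiency_expression_correlation,
    mann_whitney_u,
    relative_expression,
    student_t_two_sample,
)


def qpcr(condition, target, housekeeping=1.0, sid="s"):
    return ExpressionMeasurement(sid, condition, target, housekeeping)


class TestRelativeExpression:
    def test_thirty_percent_reduction(self):
        ms = [
            qpcr("basal", 1.0), qpcr("basal", 1.0),
            qpcr("treated:del", 0.6), qpcr("treated:del", 0.8),
        ]
        res = relative_expression(ms, "del")
        assert res.percent_change == pytest.approx(30.0)
        np.testing.assert_allclose(res.treated_normalized, [0.6, 0.8])

    def test_identical_conditions_give_zero_change(self):
        ms = [qpcr("basal", 0.9), qpcr("basal", 1.1),
              qpcr("treated:x", 0.9), qpcr("treated:x", 1.1)]
        res = relative_expression(ms, "x")
        assert res.percent_change == pytest.approx(0.0)

    def test_global_rescaling_invariance(self):
        base = [("basal", 2.0, 1.5), ("basal", 1.8, 1.2),
                ("treated:x", 1.1, 1.4), ("treated:x", 0.9, 1.1)]
        ms = [ExpressionMeasurement("s", c, t, h) for c, t, h in base]
        scaled = [ExpressionMeasurement("s", c, 10 * t, 10 * h) for c, t, h in base]
        reordered = [ms[i] for i in (3, 0, 2, 1)]
        ref = relative_expression(ms, "x").percent_change
        assert relative_expression(scaled, "x").percent_change == pytest.approx(ref)
        assert relative_expression(reordered, "x").percent_change == pytest.approx(ref)

    def test_errors(self):
        with pytest.raises(ValueError, match="positive"):
            qpcr("basal", 0.0)
        with pytest.raises(ValueError, match="replicate"):
            relative_expression([qpcr("basal", 1.0)], "x")


class TestStudentT:
    def test_identical_groups(self):
        t, p = student_t_two_sample([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_worked_example(self):
        # pooled s = 1, se = sqrt(2/3): t = -1/sqrt(2/3)
        t, p = student_t_two_sample([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-math.sqrt(1.5), abs=1e-4)  # -1.2247
        assert p == pytest.approx(0.2879, abs=1e-3)  # t CDF at |t|, df=4

    @given(
        a=st.lists(st.floats(-10, 10), min_size=2, max_size=6),
        b=st.lists(st.floats(-10, 10), min_size=2, max_size=6),
    )
    def test_sign_flip_on_swap(self, a, b):
        try:
            t_ab, p_ab = student_t_two_sample(a, b)
        except ValueError:
            return  # degenerate zero-variance draw
        t_ba, p_ba = student_t_two_sample(b, a)
        assert t_ab == pytest.approx(-t_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_insufficient_replicates(self):
        with pytest.raises(ValueError):
            student_t_two_sample([1.0], [1.0, 2.0])


def mwu_enumeration_oracle(a, b):
    """Exact two-sided p by enumerating all group-label assignments."""
    a, b = list(a), list(b)
    n_a = len(a)
    combined = a + b

    def u_stat(first):
        rest = [x for i, x in enumerate(combined) if i not in set(first)]
        picked = [combined[i] for i in first]
        return sum(x > y for x in picked for y in rest) + 0.5 * sum(
            x == y for x in picked for y in rest
        )

    observed = u_stat(range(n_a))
    n_b = len(b)
    us = [u_stat(c) for c in itertools.combinations(range(n_a + n_b), n_a)]
    mean_u = n_a * n_b / 2
    dev = abs(observed - mean_u)
    p = sum(abs(u - mean_u) >= dev - 1e-12 for u in us) / len(us)
    return observed, min(1.0, p)


class TestMannWhitney:
    def test_exact_small_sample(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_u_identity(self, rng):
        for _ in range(20):
            a = rng.standard_normal(rng.integers(1, 8))
            b = rng.standard_normal(rng.integers(1, 8))
            u_a, _ = mann_whitney_u(a, b)
            u_b, _ = mann_whitney_u(b, a)
            assert u_a + u_b == pytest.approx(len(a) * len(b))

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_exact_p_matches_enumeration_oracle(self, n, rng):
        for _ in range(10):
            vals = rng.permutation(np.arange(1.0, 2 * n + 1))  # no ties
            a, b = vals[:n], vals[n:]
            u, p = mann_whitney_u(a, b)
            u_oracle, p_oracle = mwu_enumeration_oracle(a, b)
            assert u == pytest.approx(u_oracle)
            assert p == pytest.approx(p_oracle)

    def test_identical_multisets_large_sample(self):
        a = list(range(10))
        p = mann_whitney_u(a, a)[1]
        assert p == pytest.approx(1.0, abs=0.05)  # asymptotic path with ties


class TestAlleleLog2FC:
    def _enrich(self, wt, var, factor="FOXA1"):
        out = []
        for i, w in enumerate(wt):
            out.append(AlleleEnrichment(factor, "wildtype", f"rep{i}", w))
        for i, v in enumerate(var):
            out.append(AlleleEnrichment(factor, "variant", f"rep{i}", v))
        return out

    def test_equal_twofold_and_half(self):
        res = allele_log2fc(self._enrich([2.0, 3.0], [2.0, 3.0]), "FOXA1")
        np.testing.assert_allclose(res.log2fc, 0.0)
        res = allele_log2fc(self._enrich([1.0, 2.0], [2.0, 4.0]), "FOXA1")
        assert res.mean_log2fc == pytest.approx(1.0)
        res = allele_log2fc(self._enrich([2.0, 4.0], [1.0, 2.0]), "FOXA1")
        assert res.mean_log2fc == pytest.approx(-1.0)
        assert res.paired

    def test_unpaired_fallback(self):
        enrich = self._enrich([1.0, 2.0], [2.0, 4.0])
        enrich[-1] = AlleleEnrichment("FOXA1", "variant", "other_rep", 4.0)
        res = allele_log2fc(enrich, "FOXA1")
        assert not res.paired
        # each variant replicate over the mean wild-type enrichment (1.5)
        np.testing.assert_allclose(res.log2fc,
                                   np.log2(np.array([4.0, 2.0]) / 1.5))

    def test_missing_allele(self):
        only_wt = [AlleleEnrichment("AR", "wildtype", f"r{i}", 1.0 + i)
                   for i in range(3)]
        with pytest.raises(ValueError, match="replicates per allele"):
            allele_log2fc(only_wt, "AR")

    def test_validation(self):
        with pytest.raises(ValueError):
            AlleleEnrichment("AR", "mutant", "r1", 1.0)
        with pytest.raises(ValueError):
            AlleleEnrichment("AR", "variant", "r1", 0.0)


class TestEfficiencyCorrelation:
    def test_examples(self):
        r, p = efficiency_expression_correlation([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)
        r, p = efficiency_expression_correlation([1, 2, 3], [3, 2, 1])
        assert r == pytest.approx(-1.0) and p == pytest.approx(0.0)

    def test_p_matches_scipy_reference(self, rng):
        """The t-transform p equals the independent scipy.stats.pearsonr p."""
        from scipy.stats import pearsonr

        for _ in range(10):
            x = rng.standard_normal(8)
            y = 0.5 * x + rng.standard_normal(8)
            r, p = efficiency_expression_correlation(x, y)
            ref = pearsonr(x, y)
            assert r == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_zero_correlation_small_n(self):
        r, p = efficiency_expression_correlation([0.0, 1.0, 2.0],
                                                 [1.0, 0.0, 1.0])
        assert r == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)


class TestBenjaminiHochberg:
    def test_matches_manual_adjustment(self):
        # step-up by hand: sorted [.01,.03,.04,.5] -> [.04,.06,.0533,.5],
        # then cumulative min from the right
        p = [0.01, 0.04, 0.03, 0.5]
        q = benjamini_hochberg(p)
        np.testing.assert_allclose(q, [0.04, 0.16 / 3, 0.16 / 3, 0.5])
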