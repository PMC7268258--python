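"""Unit and property tests for the symbiosis impairment score."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from catchn.depletion import (
    DepletionModel,
    call_symbiosis_genes,
    estimate_loss_rate,
    impairment_score,
    max_loss_run,
    p1_poisson,
    p2,
    p2_fraction,
)


def p1_series(lam: float, i: int) -> float:
    """Independent oracle: direct term-by-term summation in log space."""
    terms = [math.exp(-lam + s * math.log(lam) - math.lgamma(s + 1))
             if lam > 0 else (1.0 if s == 0 else 0.0)
             for s in range(i + 1)]
    return math.fsum(terms)


class TestP1:
    @pytest.mark.parametrize(
        "lam,i,expected",
        [
            (1.0, 0, math.exp(-1)),
            (20 / 6.84, 0, math.exp(-20 / 6.84)),
            (5.0, 10_000, 1.0),  # far-right tail of the CDF
            (0.0, 0, 1.0),
        ],
    )
    def test_known_values(self, lam, i, expected):
        assert p1_poisson(lam, i) == pytest.approx(expected, rel=1e-12)

    def test_matches_direct_series(self):
        for lam in (0.1, 1.0, 2.924, 10.0, 50.0):
            for i in (0, 1, 5, 20, 80, 200):
                assert abs(p1_poisson(lam, i) - p1_series(lam, i)) < 1e-12

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            p1_poisson(-1.0, 3)
        with pytest.raises(ValueError):
            p1_poisson(1.0, -3)


class TestMaxLossRun:
    @pytest.mark.parametrize(
        "inp,out,expected",
        [
            ([10, 20, 30, 40, 50], [30], (5, 1, 2)),
            ([10, 20, 30], [10, 20, 30], (3, 3, 0)),
            ([1, 2, 3, 4, 5, 6, 7], [], (7, 0, 7)),
            ([5, 1, 9], [9], (3, 1, 2)),  # unsorted input handled
        ],
    )
    def test_examples(self, inp, out, expected):
        assert max_loss_run(inp, out) == expected

    def test_output_not_subset_rejected(self):
        with pytest.raises(ValueError, match="not present"):
            max_loss_run([10, 20], [30])


class TestP2Exact:
    @pytest.mark.parametrize(
        "n,i,k,expected",
        [
            (3, 1, 2, Fraction(2, 3)),
            (4, 1, 2, Fraction(1)),
            (5, 2, 1, Fraction(1)),   # IE terms 18 - 9 + 1 = 10 over C(5,2)
            (10, 3, 0, Fraction(1)),
            (10, 8, 5, Fraction(0)),  # k > n - i
        ],
    )
    def test_reference_values(self, n, i, k, expected):
        assert p2_fraction(n, i, k) == expected
        val, method, se = p2(n, i, k)
        assert val == pytest.approx(float(expected), abs=1e-15)
        assert se is None

    def test_oracle_equivalence_full_sweep(self):
        """Inclusion-exclusion equals exhaustive enumeration exactly, and the
        single-run closed form agrees whenever at most one run can reach k."""
        for n in range(0, 13):
            for i in range(n + 1):
                for k in range(n - i + 1):
                    enum = p2_fraction(n, i, k, "enumeration")
                    ie = p2_fraction(n, i, k, "inclusion_exclusion")
                    assert ie == enum, (n, i, k)
                    if 2 * k > n - i:
                        cf = p2_fraction(n, i, k, "closed_form")
                        assert cf == enum, (n, i, k)

    def test_closed_form_guard(self):
        with pytest.raises(ValueError, match="closed form"):
            p2_fraction(10, 2, 3, "closed_form")  # k <= (n-i)/2

    def test_monotone_nonincreasing_in_k(self):
        for n, i in [(15, 4), (30, 10), (200, 40)]:
            vals = [p2(n, i, k)[0] for k in range(n - i + 1)]
            assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_extreme_k_consistency(self):
        # k = n - i: all losses in one run, (i+1) placements of that run
        for n, i in [(8, 3), (20, 5), (100, 2)]:
            expected = Fraction(i + 1, math.comb(n, i)) * math.comb(i, i)
            assert p2_fraction(n, i, n - i) == expected

    def test_large_n_log_space_matches_exact_integers(self):
        # beyond the integer-arithmetic cutoff the log-gamma path takes over
        from catchn.depletion import _p2_inclusion_exclusion_log

        # alternating-sum cancellation limits the log path to ~1e-7 relative
        for n, i, k in [(500, 60, 10), (2500, 300, 15), (2500, 10, 400)]:
            exact = float(p2_fraction(n, i, k))
            assert _p2_inclusion_exclusion_log(n, i, k) == pytest.approx(
                exact, rel=1e-6, abs=1e-300
            )


class TestP2MonteCarlo:
    def test_agrees_with_exact_within_4_se(self):
        grid = [(100, 14, 15), (100, 30, 8), (300, 44, 15), (300, 10, 40)]
        for n, i, k in grid:
            exact = p2(n, i, k)[0]
            mc, method, se = p2(n, i, k, method="monte_carlo",
                                reps=100_000, seed=123)
            assert method == "monte_carlo"
            assert abs(mc - exact) <= 4 * max(se, 1e-12), (n, i, k)

    def test_seeded_reproducibility(self):
        a = p2(100, 20, 10, method="monte_carlo", reps=5_000, seed=5)
        b = p2(100, 20, 10, method="monte_carlo", reps=5_000, seed=5)
        assert a == b


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    n=st.integers(1, 40),
    data=st.data(),
)
def test_p2_is_probability_and_k_edge_cases(n, data):
    i = data.draw(st.integers(0, n))
    k = data.draw(st.integers(0, n - i))
    v = p2_fraction(n, i, k)
    assert 0 <= v <= 1
    if k == 0:
        assert v == 1
    if i == 0 and k > 0:
        assert v == (1 if k <= n else 0)


class TestLossRate:
    def test_printed_library_totals(self):
        genes = {"all": (750_128, 99_623)}
        assert estimate_loss_rate(genes) == pytest.approx(7.530, abs=5e-4)

    def test_full_recovery_gives_one(self):
        assert estimate_loss_rate({"a": (10, 10), "b": (5, 5)}) == 1.0

    def test_no_recovery_rejected(self):
        with pytest.raises(ValueError, match="no recovered"):
            estimate_loss_rate({"a": (10, 0)})

    def test_neutral_subset_used_when_given(self):
        genes = {"neutral": (100, 50), "depleted": (100, 1)}
        assert estimate_loss_rate(genes, ["neutral"]) == 2.0


class TestImpairmentScore:
    def test_total_loss_composes_both_closed_forms(self):
        s = impairment_score(20, 0, 20, 6.84)
        assert s.p2 == 1.0
        assert s.score == pytest.approx(math.exp(-20 / 6.84), rel=1e-12)

    def test_full_recovery_not_depleted(self):
        s = impairment_score(20, 20, 0, 6.84)
        assert s.p2 == 1.0
        assert s.score > 0.9

    def test_recovery_term_monotone_and_run_term_monotone(self):
        # p1 falls as recovery worsens at fixed n; p2 falls as the observed
        # run grows at fixed (n, i).  (The full product is not monotone in i
        # along k = n - i: p2(n, i, n-i) = (i+1)/C(n, i) rises again as
        # i -> 0 while p1 keeps falling.)
        p1s = [impairment_score(20, i, 20 - i, 6.84).p1 for i in range(20, -1, -1)]
        assert all(a >= b - 1e-12 for a, b in zip(p1s, p1s[1:]))
        p2s = [impairment_score(30, 10, k, 6.84).p2 for k in range(0, 21)]
        assert all(a >= b - 1e-12 for a, b in zip(p2s, p2s[1:]))

    def test_no_input_sites_rejected(self):
        with pytest.raises(ValueError, match="no_data"):
            impairment_score(0, 0, 0, 6.84)


class TestCalls:
    def test_all_scores_one_gives_empty_set(self):
        df = pd.DataFrame({"score": [1.0, 1.0]}, index=["a", "b"])
        out = call_symbiosis_genes(df)
        assert not out["symbiosis_gene"].any()

    def test_alpha_one_flags_everything(self):
        df = pd.DataFrame({"score": [0.2, 0.99]}, index=["a", "b"])
        out = call_symbiosis_genes(df, alpha=1.0)
        assert out["symbiosis_gene"].all()

    def test_bh_adjustment_is_less_greedy(self):
        df = pd.DataFrame(
            {"score": [0.001, 0.04, 0.045, 0.9]}, index=list("abcd")
        )
        raw = call_symbiosis_genes(df, alpha=0.05, correction="none")
        bh = call_symbiosis_genes(df, alpha=0.05, correction="benjamini_hochberg")
        assert raw["symbiosis_gene"].sum() >= bh["symbiosis_gene"].sum()


class TestModelResults:
    def test_fit_from_nik_table(self):
        data = pd.DataFrame(
            {"n": [30, 30], "i": [4, 0], "k": [10, 30]}, index=["neutral", "hit"]
        )
        res = DepletionModel(data).fit(loss_rate=6.84)
        assert res.table.loc["hit", "score"] < res.table.loc["neutral", "score"]
        assert "hit" in res.summary()

    def test_inconsistent_rows_rejected(self):
        bad = pd.DataFrame({"n": [5], "i": [6], "k": [0]}, index=["g"])
        with pytest.raises(ValueError, match="inconsistent"):
            DepletionModel(bad)
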