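"""Bland–Altman statistics and the Wilcoxon signed-rank test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cdwi import (
    MethodComparison,
    PairedSummaries,
    bland_altman,
    scheme_table,
    wilcoxon_signed_rank,
)


def exact_wilcoxon_p(d):
    """Brute-force two-sided p by enumerating all sign assignments.

    For tie-free, zero-free differences: the null distribution of T+ (sum of
    ranks of positive differences) over all 2^n equiprobable sign vectors;
    p = min(1, 2·min(P(T+ ≤ t), P(T+ ≥ t))).
    """
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    t_obs = ranks[d > 0].sum()
    ts = np.array([np.sum(ranks[list(signs)])
                   for signs in itertools.product([False, True], repeat=n)])
    p_low = np.mean(ts <= t_obs)
    p_high = np.mean(ts >= t_obs)
    return min(1.0, 2.0 * min(p_low, p_high))


class TestBlandAltman:
    def test_identical_arms_zero_difference(self):
        pairs = PairedSummaries(a=np.arange(5.0), b=np.arange(5.0))
        res = bland_altman(pairs)
        assert res.mean_diff == 0.0
        assert res.sd_diff == 0.0
        assert res.loa_low == res.loa_high == 0.0

    def test_two_point_closed_form(self):
        pairs = PairedSummaries(a=np.array([1.0, -1.0]),
                                b=np.array([0.0, 0.0]))
        res = bland_altman(pairs)
        assert res.mean_diff == pytest.approx(0.0)
        assert res.sd_diff == pytest.approx(np.sqrt(2.0))
        assert res.loa_high == pytest.approx(1.96 * np.sqrt(2.0))
        assert res.loa_low == pytest.approx(-1.96 * np.sqrt(2.0))

    def test_recovers_injected_offset(self):
        rng = np.random.default_rng(8)
        base = rng.normal(1.5e-3, 1e-4, 30)
        delta = 0.06e-3
        pairs = PairedSummaries(a=base + delta,
                                b=base + rng.normal(0, 1e-5, 30))
        res = bland_altman(pairs)
        assert res.mean_diff == pytest.approx(delta, abs=3e-5 / np.sqrt(30) * 3)

    def test_antisymmetry(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=12), rng.normal(size=12)
        r1 = bland_altman(PairedSummaries(a=a, b=b))
        r2 = bland_altman(PairedSummaries(a=b, b=a))
        assert r1.mean_diff == pytest.approx(-r2.mean_diff)
        assert r1.sd_diff == pytest.approx(r2.sd_diff)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            PairedSummaries(a=np.array([1.0]), b=np.array([2.0]))


class TestWilcoxon:
    def test_all_positive_n6_exact(self):
        pairs = PairedSummaries(a=np.arange(1.0, 7.0), b=np.zeros(6))
        _, p = wilcoxon_signed_rank(pairs)
        assert p == pytest.approx(2.0 / 64.0)

    def test_identical_arms_p_one(self):
        pairs = PairedSummaries(a=np.ones(6), b=np.ones(6))
        with pytest.warns(UserWarning, match="zero"):
            stat, p = wilcoxon_signed_rank(pairs)
        assert p == 1.0

    @pytest.mark.parametrize("n", range(5, 11))
    def test_matches_enumeration_oracle(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(17):
            d = rng.normal(size=n)
            pairs = PairedSummaries(a=d, b=np.zeros(n))
            _, p = wilcoxon_signed_rank(pairs)
            assert p == pytest.approx(exact_wilcoxon_p(d), abs=1e-12)

    def test_symmetric_differences_match_oracle(self):
        d = np.array([1.0, -1.1, 2.0, -2.2, 0.5, -0.4])
        pairs = PairedSummaries(a=d, b=np.zeros(6))
        _, p = wilcoxon_signed_rank(pairs)
        assert p == pytest.approx(exact_wilcoxon_p(d), abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=-10, max_value=10,
                              allow_nan=False).filter(lambda x: abs(x) > 1e-6),
                    min_size=5, max_size=9),
           st.floats(min_value=0.1, max_value=50),
           st.floats(min_value=-100, max_value=100))
    def test_invariant_under_positive_affine_transform(self, diffs, scale,
                                                       shift):
        """Signed-rank p depends only on signs and |difference| ranks, so any
        increasing affine map of both arms leaves it unchanged.  (General
        monotone maps can reorder the |difference| ranks and change p; only
        the sign test is invariant to those.)"""
        d = np.array(diffs)
        if len(np.unique(np.abs(d))) < len(d):
            return
        a = d + 100.0
        b = np.full_like(d, 100.0)
        _, p1 = wilcoxon_signed_rank(PairedSummaries(a=a, b=b))
        _, p2 = wilcoxon_signed_rank(
            PairedSummaries(a=scale * a + shift, b=scale * b + shift))
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_zeros_dropped_before_ranking(self):
        d = np.array([0.0, 0.0, 1.0, 2.0, -3.0, 4.0, 5.0])
        pairs = PairedSummaries(a=d, b=np.zeros(7))
        _, p = wilcoxon_signed_rank(pairs)
        assert p == pytest.approx(exact_wilcoxon_p(d), abs=1e-12)


class TestSchemeTable:
    def _summaries(self, md_a=1.59e-3, md_b=1.53e-3, n=30, jitter=0.0):
        rng = np.random.default_rng(10)
        rows = []
        for i in range(n):
            unit = f"s{i // 3}/slice{i % 3}"
            rows.append({"scheme": "A", "unit": unit,
                         "md": md_a + jitter * rng.normal(),
                         "fa": 0.34, "abs_e2a": 25.0})
            rows.append({"scheme": "B", "unit": unit,
                         "md": md_b + jitter * rng.normal(),
                         "fa": 0.34, "abs_e2a": 25.0})
        return pd.DataFrame(rows)

    def test_identical_schemes_zero_deltas(self):
        df = self._summaries(md_a=1.5e-3, md_b=1.5e-3)
        per_scheme, diffs = scheme_table(df, schemes=("A", "B"))
        assert diffs.d_md[0] == pytest.approx(0.0, abs=1e-18)
        assert diffs.d_md_pct[0] == pytest.approx(0.0, abs=1e-12)

    def test_table_difference_arithmetic(self):
        """ΔMD 1.59 vs 1.53 (×10⁻³): Δ = 0.06e-3, Δ% ≈ 4% of reference."""
        df = self._summaries()
        per_scheme, diffs = scheme_table(df, schemes=("A", "B"))
        assert diffs.d_md[0] == pytest.approx(0.06e-3, rel=1e-9)
        assert diffs.d_md_pct[0] == pytest.approx(100 * 0.06 / 1.53, rel=1e-9)
        assert round(diffs.d_md_pct[0]) == 4

    def test_three_percent_rounding_convention(self):
        df = self._summaries(md_a=1.54e-3, md_b=1.59e-3)
        _, diffs = scheme_table(df, schemes=("A", "B"))
        assert round(diffs.d_md_pct[0]) == -3

    def test_missing_scheme_flagged(self):
        df = self._summaries()
        _, diffs = scheme_table(df, schemes=("A", "B", "C"),
                                comparisons=(("A", "C"),))
        assert diffs.incomplete[0]

    def test_method_comparison_model_fit(self):
        df = self._summaries(jitter=1e-5)
        res = MethodComparison(df, "md", "A", "B").fit()
        assert res.n == 30
        assert res.mean_diff == pytest.approx(0.06e-3, abs=2e-5)
        assert "Wilcoxon" in res.summary()


def test_bland_altman_plot_written(tmp_path):
    from cdwi.compare import plot_bland_altman
    rng = np.random.default_rng(3)
    res = bland_altman(PairedSummaries(a=rng.normal(size=30),
                                       b=rng.normal(size=30), metric="md"))
    out = tmp_path / "ba.png"
    plot_bland_altman(res, out, slice_labels=["basal", "mid", "apical"] * 10)
    assert out.exists() and out.stat().st_size > 0
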