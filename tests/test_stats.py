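"""Spearman correlation against independent oracles, CI/p behaviour, and
the analysis panel."""

import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from nervequant.stats import (
    CorrelationResult,
    moderate_correlation_flag,
    render_report,
    run_panel,
    spearman,
)


def brute_force_spearman(x, y):
    """Independent oracle: average ranks computed explicitly, then the
    textbook Pearson formula on the ranks."""

    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3], [1, 2, 3]).r == pytest.approx(1.0)
        assert spearman([1, 2, 3], [3, 2, 1]).r == pytest.approx(-1.0)

    def test_sum_of_squared_rank_differences_example(self):
        # d = (1,-1,1,-1,0), sum d^2 = 4, r = 1 - 6*4/(5*24) = 0.8
        res = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.r == pytest.approx(0.8)

    def test_matches_brute_force_on_all_permutations_of_n5(self):
        x = [1, 2, 3, 4, 5]
        for perm in permutations(x):
            ours = spearman(x, perm).r
            assert ours == pytest.approx(brute_force_spearman(x, perm), abs=1e-12)
            assert ours == pytest.approx(sps.spearmanr(x, perm).statistic, abs=1e-12)

    def test_handles_ties_like_scipy(self):
        x = [1, 1, 2, 3, 3, 4]
        y = [2, 1, 1, 3, 4, 4]
        assert spearman(x, y).r == pytest.approx(sps.spearmanr(x, y).statistic, abs=1e-12)

    def test_fisher_z_confidence_interval_closed_form(self):
        res = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])  # r = 0.8, n = 5
        lo = math.tanh(math.atanh(0.8) - 1.959963984540054 / math.sqrt(2))
        hi = math.tanh(math.atanh(0.8) + 1.959963984540054 / math.sqrt(2))
        assert res.ci_low == pytest.approx(lo, abs=1e-9)
        assert res.ci_high == pytest.approx(hi, abs=1e-9)
        assert (round(res.ci_low, 2), round(res.ci_high, 2)) == (-0.28, 0.99)

    def test_p_matches_t_approximation(self):
        rng = np.random.default_rng(3)
        x, y = rng.random(30), rng.random(30)
        res = spearman(x, y)
        assert res.p == pytest.approx(sps.spearmanr(x, y).pvalue, rel=1e-9)

    def test_exact_permutation_p_small_n(self):
        # only the identity and the full reversal reach |r| = 1: p = 2/24
        res = spearman([1, 2, 3, 4], [1, 2, 3, 4], exact_p=True)
        assert res.p == pytest.approx(2 / 24)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1], [1, 2, 3])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            spearman([1, 2], [1, 2])

    def test_nan_pairs_dropped(self):
        res = spearman([1, 2, 3, np.nan], [1, 2, 3, 4])
        assert res.n == 3

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_symmetry_and_monotone_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.random(12), rng.random(12)
        r_xy = spearman(x, y).r
        assert spearman(y, x).r == pytest.approx(r_xy, abs=1e-12)
        # a strictly increasing transform leaves ranks unchanged
        assert spearman(np.exp(3 * x), y).r == pytest.approx(r_xy, abs=1e-12)


class TestModerateFlag:
    @pytest.mark.parametrize("r,expected", [(0.5, True), (-0.6, True), (0.49, False)])
    def test_cutoff(self, r, expected):
        res = CorrelationResult(r=r, ci_low=-1, ci_high=1, p=0.5, n=10)
        assert moderate_correlation_flag(res) is expected


class TestRunPanel:
    @staticmethod
    def _merged(n=20, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "study_id": [f"S{i}" for i in range(n)],
                "cns_disease": ["yes"] * 5 + ["unclear"] * 3 + ["no"] * (n - 8),
                "serum_nfl": rng.lognormal(2, 0.5, n),
                "tissue_nfl": rng.lognormal(5, 0.5, n),
                "serum_csf_ratio": rng.random(n),
                "serum_z": rng.normal(size=n),
                "acute_composite": rng.random(n) * 100,
                "nf70_pct_area": rng.random(n) * 30,
                "fiber_density": rng.random(n) * 700,
            }
        )

    def test_subgroup_restriction_never_increases_n(self):
        panel = run_panel(self._merged())
        wide = panel.pivot_table(index=["x", "y"], columns="subgroup", values="n")
        assert (wide["no_cns"] <= wide["all"]).all()

    def test_subgroup_counts_respect_unclear_rule(self):
        merged = self._merged()
        keep_unclear = run_panel(merged)
        drop_unclear = run_panel(merged, exclude_unclear_cns=True)
        assert keep_unclear.query("subgroup == 'no_cns'")["n"].max() == 15
        assert drop_unclear.query("subgroup == 'no_cns'")["n"].max() == 12

    def test_missing_variable_is_an_error(self):
        with pytest.raises(ValueError, match="lacks variables"):
            run_panel(self._merged().drop(columns=["serum_z"]))

    def test_pairwise_complete_n(self):
        merged = self._merged()
        merged.loc[:4, "serum_csf_ratio"] = np.nan
        panel = run_panel(merged)
        row = panel.query("x == 'serum_csf_ratio' and subgroup == 'all'").iloc[0]
        assert row["n"] == 15


class TestRenderReport:
    def test_report_is_deterministic(self):
        panel = run_panel(TestRunPanel._merged())
        assert render_report(panel) == render_report(panel)

    def test_formats_result_row(self):
        panel = pd.DataFrame(
            [{"x": "serum_nfl", "y": "acute_composite", "subgroup": "all",
              "r": 0.8, "ci_low": -0.28, "ci_high": 0.99, "p": 0.104, "n": 5}]
        )
        text = render_report(panel)
        assert "r = 0.80 [-0.28 to 0.99]" in text
        assert "n = 5" in text

    def test_empty_panel_renders_header_only(self):
        panel = pd.DataFrame(columns=["x", "y", "subgroup", "r", "ci_low", "ci_high", "p", "n"])
        text = render_report(panel)
        assert "correlation report" in text.lower()
        assert len(text.splitlines()) == 4
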