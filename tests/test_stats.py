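"""Rank-sum engine against an exhaustive permutation oracle, summaries,
Bonferroni, comparison schemes and composition histograms."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from marginspec.stats import (
    bonferroni,
    composition_histogram,
    comparisons_frame,
    ranksum_test,
    run_scheme,
    summarize,
)


def permutation_ranksum_p(x, y):
    """Independent oracle: exact two-sided rank-sum P by enumerating every
    assignment of the pooled midranks to group x."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    order = pooled.argsort(kind="mergesort")
    ranks = np.empty_like(pooled)
    # midranks for ties
    sorted_vals = pooled[order]
    r = np.arange(1.0, pooled.size + 1)
    i = 0
    while i < pooled.size:
        j = i
        while j + 1 < pooled.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        r[i : j + 1] = (i + j + 2) / 2.0
        i = j + 1
    ranks[order] = r
    nx = x.size
    observed = ranks[:nx].sum()
    mean = nx * (pooled.size + 1) / 2.0
    obs_dev = abs(observed - mean)
    count = 0
    total = 0
    for combo in itertools.combinations(range(pooled.size), nx):
        stat = ranks[list(combo)].sum()
        total += 1
        if abs(stat - mean) >= obs_dev - 1e-9:
            count += 1
    return count / total


class TestSummarize:
    def test_small_vector_by_definition(self):
        s = summarize([1.0, 2.0, 3.0])
        assert s.median == 2.0 and s.mad == 1.0

    def test_mad_robust_to_single_outlier(self):
        """[1,2,3,100]: median 2.5, |x - 2.5| = {1.5, .5, .5, 97.5}, MAD 1.0."""
        s = summarize([1.0, 2.0, 3.0, 100.0])
        assert s.median == 2.5 and s.mad == 1.0

    def test_constant_vector_degenerate(self):
        s = summarize([4.0] * 7)
        assert s.mad == 0.0 and s.iqr == 0.0
        assert s.whisker_lo == s.whisker_hi == 4.0

    def test_whiskers_at_furthest_datum_within_fence(self):
        x = [1.0, 2.0, 3.0, 4.0, 100.0]
        s = summarize(x)
        assert s.whisker_hi == 4.0  # 100 lies beyond Q3 + 1.5 IQR
        assert s.whisker_lo == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestRanksum:
    def test_exact_small_sample(self):
        """x=[1,2], y=[3,4]: the most extreme of the C(4,2)=6 splits on
        either side -> two-sided P = 2/6."""
        c = ranksum_test([1.0, 2.0], [3.0, 4.0])
        assert c.p_nominal == pytest.approx(1 / 3)

    def test_identical_samples_p_one(self):
        c = ranksum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert c.p_nominal == pytest.approx(1.0)

    def test_large_shift_is_overwhelming(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(200)
        y = rng.standard_normal(200) + 1.0
        c = ranksum_test(x, y)
        assert c.p_nominal < 1e-6

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        nx=st.integers(2, 5),
        ny=st.integers(2, 5),
        seed=st.integers(0, 10_000),
    )
    def test_agrees_with_exhaustive_enumeration(self, nx, ny, seed):
        """Oracle equivalence for all tie-free inputs with combined n <= 10."""
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(nx)
        y = rng.standard_normal(ny)
        c = ranksum_test(x, y)
        assert c.p_nominal == pytest.approx(permutation_ranksum_p(x, y), abs=1e-12)

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            ranksum_test([1.0], [2.0, 3.0])


class TestBonferroni:
    def test_marginal_nominal_p_loses_significance_at_m3(self):
        assert bonferroni(0.045, 3) == pytest.approx(0.135)

    def test_capped_at_one(self):
        assert bonferroni(0.2, 9) == 1.0

    def test_identity_at_m1(self):
        assert bonferroni(0.37, 1) == 0.37

    @settings(derandomize=True, max_examples=40)
    @given(p=st.floats(0.0, 1.0), m1=st.integers(1, 9), m2=st.integers(1, 9))
    def test_adjusted_p_nondecreasing_in_m(self, p, m1, m2):
        lo, hi = sorted((m1, m2))
        assert bonferroni(p, lo) <= bonferroni(p, hi)


def _cohort_frame(rng, groups):
    """groups: list of (top, tissue, depth, meno, n, musp_shift)."""
    rows = []
    for top, tissue, depth, meno, n, shift in groups:
        for _ in range(n):
            rows.append(
                {
                    "top_class": top,
                    "tissue_class": tissue,
                    "depth_category": depth,
                    "menopause": meno,
                    "mean_musp": 7.0 + shift + rng.standard_normal(),
                    "c_bcar": 17.0 + rng.standard_normal(),
                    "thb": 32.0 + 5 * rng.standard_normal(),
                }
            )
    return pd.DataFrame(rows)


class TestSchemes:
    def test_normal_types_scheme_has_three_pairs_per_parameter(self):
        rng = np.random.default_rng(0)
        df = _cohort_frame(
            rng,
            [("normal", t, None, "post", 20, 0.0) for t in ("FG", "FA", "A")],
        )
        comps, summaries, skipped = run_scheme(df, "normal_types_m3")
        per_param = comparisons_frame(comps).groupby("parameter").size()
        assert (per_param == 3).all()
        assert all(c.m == 3 for c in comps)
        assert not skipped

    def test_depth_scheme_has_nine_pairs_per_parameter(self):
        rng = np.random.default_rng(0)
        groups = [("normal", t, None, "post", 15, 0.0) for t in ("FG", "FA", "A")]
        groups += [
            ("malignant", "IDC", d, "post", 8, 1.0)
            for d in ("0 mm", "0+-1 mm", "1+-2 mm")
        ]
        df = _cohort_frame(np.random.default_rng(1), groups)
        comps, _, skipped = run_scheme(df, "depth_m9")
        per_param = comparisons_frame(comps).groupby("parameter").size()
        assert (per_param == 9).all()
        assert all(c.m == 9 for c in comps)

    def test_empty_stratum_skipped_with_warning(self):
        rng = np.random.default_rng(2)
        groups = [("normal", t, None, "post", 12, 0.0) for t in ("FG", "FA", "A")]
        groups += [("malignant", "IDC", "0 mm", "post", 2, 1.0)]  # below min_n
        df = _cohort_frame(rng, groups)
        comps, _, skipped = run_scheme(df, "depth_m9")
        assert skipped  # sparse cells logged, not fatal
        assert all("0+-1 mm" not in f"{c.group_a}{c.group_b}" for c in comps)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            run_scheme(pd.DataFrame(), "nope")

    def test_null_cohort_type_one_error_controlled(self):
        """With identical generating distributions, the fraction of adjusted
        P < 0.05 stays at or below the nominal level (quick 120-replicate
        check; the full 500-replicate calibration runs in the acceptance
        suite)."""
        rng = np.random.default_rng(3)
        hits = total = 0
        for _ in range(120):
            df = _cohort_frame(
                rng,
                [("normal", t, None, "post", 15, 0.0) for t in ("FG", "FA", "A")],
            )
            comps, _, _ = run_scheme(df, "normal_types_m3")
            hits += sum(c.p_adjusted < 0.05 for c in comps)
            total += len(comps)
        assert hits / total <= 0.05


class TestComposition:
    def test_multinomial_recovery_post_preset(self):
        rng = np.random.default_rng(4)
        n = 300
        draws = rng.choice(["A", "FA", "FG"], size=n, p=[0.84, 0.15, 0.01])
        df = pd.DataFrame(
            {
                "top_class": "normal",
                "menopause": "post",
                "tissue_class": draws,
            }
        )
        pct = composition_histogram(df, "post")
        assert pct["A"] == pytest.approx(84.0, abs=5.0)
        assert pct["FA"] == pytest.approx(15.0, abs=5.0)
        assert sum(pct.values()) == pytest.approx(100.0)

    def test_single_class_cohort(self):
        df = pd.DataFrame(
            {"top_class": ["normal"] * 5, "menopause": ["pre"] * 5,
             "tissue_class": ["A"] * 5}
        )
        pct = composition_histogram(df, "pre")
        assert pct == {"FG": 0.0, "FA": 0.0, "A": 100.0}

    def test_pre_menopausal_ordering_at_large_n(self):
        rng = np.random.default_rng(5)
        draws = rng.choice(["A", "FA", "FG"], size=4000, p=[0.66, 0.14, 0.20])
        df = pd.DataFrame(
            {"top_class": "normal", "menopause": "pre", "tissue_class": draws}
        )
        pct = composition_histogram(df, "pre")
        assert pct["A"] > pct["FG"] > pct["FA"]

    def test_empty_restriction_rejected(self):
        df = pd.DataFrame(
            {"top_class": ["malignant"], "menopause": ["pre"],
             "tissue_class": ["IDC"]}
        )
        with pytest.raises(ValueError):
            composition_histogram(df, "pre")
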