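"""Robust group summaries, rank-sum tests and the stratified comparison schemes.

Group distributions are summarized nonparametrically (median, unscaled MAD,
quartiles, Tukey whiskers at 1.5·IQR). Pairwise group contrasts use the
two-sided Wilcoxon rank-sum (Mann–Whitney) test — exact enumeration for small
tie-free samples, normal approximation with tie and continuity corrections
otherwise — with Bonferroni adjustment whose factor m is fixed by the
comparison scheme: 1 for the two-group malignant-vs-normal contrast, 3 for
the three normal tissue types, 6 for the normal-plus-disease variants, 9 for
the depth-by-normal-type grid, 1 for the pre/post menopausal contrast.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

__all__ = [
    "GroupSummary",
    "PairwiseComparison",
    "summarize",
    "ranksum_test",
    "bonferroni",
    "run_scheme",
    "composition_histogram",
    "SCHEMES",
]

#: extracted parameters compared in every scheme
PARAMETERS = ("mean_musp", "c_bcar", "thb")


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    median: float
    mad: float  # unscaled median absolute deviation
    q1: float
    q3: float
    iqr: float
    whisker_lo: float
    whisker_hi: float

    def __post_init__(self) -> None:
        if self.mad < 0 or not (self.q1 <= self.median <= self.q3):
            raise ValueError("inconsistent summary")


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    parameter: str
    n_a: int
    n_b: int
    statistic: float  # rank-sum of group A
    p_nominal: float
    m: int
    p_adjusted: float
    median_a: float
    median_b: float
    mad_a: float
    mad_b: float


def summarize(values, label: str = "") -> GroupSummary:
    """Median, unscaled MAD, quartiles and Tukey 1.5·IQR whiskers."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty group")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    q1, q3 = (float(v) for v in np.percentile(x, [25.0, 75.0]))
    iqr = q3 - q1
    in_lo = x[x >= q1 - 1.5 * iqr]
    in_hi = x[x <= q3 + 1.5 * iqr]
    return GroupSummary(
        label=label,
        n=int(x.size),
        median=med,
        mad=mad,
        q1=q1,
        q3=q3,
        iqr=iqr,
        whisker_lo=float(in_lo.min()),
        whisker_hi=float(in_hi.max()),
    )


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return np.unique(pooled).size < pooled.size


def ranksum_test(x, y, group_a: str = "A", group_b: str = "B",
                 parameter: str = "", m: int = 1) -> PairwiseComparison:
    """Two-sided Wilcoxon rank-sum test with Bonferroni factor ``m``.

    Exact null enumeration when the combined sample size is at most 12 and
    there are no ties; otherwise the normal approximation with midranks, tie
    variance correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    method = "exact" if (x.size + y.size <= 12 and not _has_ties(x, y)) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method,
                       use_continuity=True)
    u = float(res.statistic)  # U of group x
    ranksum = u + x.size * (x.size + 1) / 2.0
    return PairwiseComparison(
        group_a=group_a,
        group_b=group_b,
        parameter=parameter,
        n_a=int(x.size),
        n_b=int(y.size),
        statistic=ranksum,
        p_nominal=float(res.pvalue),
        m=m,
        p_adjusted=bonferroni(float(res.pvalue), m),
        median_a=float(np.median(x)),
        median_b=float(np.median(y)),
        mad_a=float(np.median(np.abs(x - np.median(x)))),
        mad_b=float(np.median(np.abs(y - np.median(y)))),
    )


def bonferroni(p: float, m: int) -> float:
    """min(1, m·p)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


# ---------------------------------------------------------------------------
# comparison schemes
# ---------------------------------------------------------------------------

def _groups_malignant_vs_normal(df):
    return {"malignant": df[df.top_class == "malignant"],
            "normal": df[df.top_class == "normal"]}, \
        [("malignant", "normal")], 1


def _groups_normal_types(df):
    g = {c: df[(df.top_class == "normal") & (df.tissue_class == c)]
         for c in ("FG", "FA", "A")}
    return g, list(itertools.combinations(g, 2)), 3


def _groups_variants(df):
    g = {c: df[(df.top_class == "normal") & (df.tissue_class == c)]
         for c in ("FG", "FA", "A")}
    for c in ("IDC", "DCIS"):
        g[c] = df[df.tissue_class == c]
    # the six disease-vs-normal-type contrasts
    pairs = [(d, n) for d in ("IDC", "DCIS") for n in ("FG", "FA", "A")]
    return g, pairs, 6


def _groups_depth(df):
    g = {c: df[(df.top_class == "normal") & (df.tissue_class == c)]
         for c in ("FG", "FA", "A")}
    for d in ("0 mm", "0+-1 mm", "1+-2 mm"):
        g[d] = df[(df.top_class == "malignant") & (df.depth_category == d)]
    pairs = [(d, n) for d in ("0 mm", "0+-1 mm", "1+-2 mm")
             for n in ("FG", "FA", "A")]
    return g, pairs, 9


def _groups_menopause(df):
    g = {s: df[(df.top_class == "normal") & (df.menopause == s)]
         for s in ("pre", "post")}
    return g, [("pre", "post")], 1


SCHEMES = {
    "malignant_vs_normal": _groups_malignant_vs_normal,
    "normal_types_m3": _groups_normal_types,
    "variants_m6": _groups_variants,
    "depth_m9": _groups_depth,
    "menopause_normal": _groups_menopause,
}


def run_scheme(cohort_df: pd.DataFrame, scheme: str,
               parameters=PARAMETERS, min_n: int = 3):
    """All pairwise comparisons of one stratification scheme.

    ``cohort_df`` needs columns ``top_class``, ``tissue_class``,
    ``depth_category``, ``menopause`` plus the extracted parameters. Strata
    with fewer than ``min_n`` sites are skipped with a logged warning
    (mirroring the exclusion of sparsely populated disease/depth cells).

    Returns ``(comparisons, summaries, skipped)``.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(SCHEMES)}")
    groups, pairs, m = SCHEMES[scheme](cohort_df)
    comparisons: list[PairwiseComparison] = []
    summaries: dict[tuple[str, str], GroupSummary] = {}
    skipped: list[str] = []
    for param in parameters:
        for label, sub in groups.items():
            vals = sub[param].dropna().to_numpy()
            if vals.size:
                summaries[(param, label)] = summarize(vals, label=label)
        for ga, gb in pairs:
            xa = groups[ga][param].dropna().to_numpy()
            xb = groups[gb][param].dropna().to_numpy()
            if xa.size < min_n or xb.size < min_n:
                skipped.append(
                    f"{scheme}/{param}: {ga} vs {gb} skipped "
                    f"(n = {xa.size}/{xb.size} below {min_n})"
                )
                continue
            comparisons.append(
                ranksum_test(xa, xb, group_a=ga, group_b=gb,
                             parameter=param, m=m)
            )
    return comparisons, summaries, skipped


def comparisons_frame(comparisons) -> pd.DataFrame:
    """Tabular view of a list of pairwise comparisons."""
    return pd.DataFrame([c.__dict__ for c in comparisons])


def plot_group_boxplots(summaries, parameter: str, ax=None):
    """Boxplot-style panel from precomputed group summaries.

    Draws median/quartile/whisker glyphs for every group summary of one
    parameter (the robust five-number summaries the analysis reports), so a
    figure can be produced without re-touching the raw per-site values.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(summaries) + 1, 4))
    items = [(lab, s) for (par, lab), s in summaries.items() if par == parameter]
    if not items:
        raise ValueError(f"no summaries for parameter {parameter!r}")
    for i, (label, s) in enumerate(items):
        ax.add_patch(
            plt.Rectangle((i - 0.3, s.q1), 0.6, s.iqr, fill=False, lw=1.2)
        )
        ax.hlines(s.median, i - 0.3, i + 0.3, lw=2)
        ax.vlines(i, s.whisker_lo, s.q1, lw=1)
        ax.vlines(i, s.q3, s.whisker_hi, lw=1)
    ax.set_xticks(range(len(items)), [lab for lab, _ in items])
    ax.set_ylabel(parameter)
    return ax


def composition_histogram(cohort_df: pd.DataFrame, status: str):
    """Percent composition of {FG, FA, A} among normal sites of one status.

    Returns a dict of full-precision percentages summing to 100; display
    rounding is left to callers.
    """
    if status not in ("pre", "post"):
        raise ValueError("status must be 'pre' or 'post'")
    sub = cohort_df[
        (cohort_df.top_class == "normal")
        & (cohort_df.menopause == status)
        & (cohort_df.tissue_class.isin(["FG", "FA", "A"]))
    ]
    n = len(sub)
    if n == 0:
        raise ValueError(f"no {status}-menopausal FG/FA/A sites")
    return {
        c: 100.0 * (sub.tissue_class == c).sum() / n
        for c in ("FG", "FA", "A")
    }
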