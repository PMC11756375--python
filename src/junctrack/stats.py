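"""Distribution summaries and group comparisons.

Box summaries follow the box-and-whisker convention used throughout the
analyses: box edges at the 25th/75th percentiles, whiskers to the most
extreme values within 1.5× the interquartile range, points beyond flagged
as outliers.  Comparisons delegate to scipy/statsmodels; the Dunn–Šidák
post hoc after Kruskal–Wallis is implemented here (rank-based pairwise z
tests with Šidák correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Percentile interpolation: linear on Weibull plotting positions
#: (h = p·(n+1)); recorded in every summary so the convention is explicit.
PERCENTILE_METHOD = "weibull"

SUPPORTED_TESTS = ("t", "KS", "ANOVA+TukeyKramer", "KruskalWallis+DunnSidak")


def significance_stars(p: float) -> str:
    """Figure annotation for a p-value (**** = p < 0.0001)."""
    if not np.isfinite(p):
        return "n/a"
    for thr, mark in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
        if p < thr:
            return mark
    return "ns"


@dataclass
class BoxSummary:
    """Median/quartile/whisker/outlier summary of one group."""

    label: str
    n: int
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: np.ndarray
    percentile_method: str = PERCENTILE_METHOD


@dataclass
class GroupComparison:
    """Result of comparing value groups: summaries plus the chosen test."""

    summaries: list[BoxSummary]
    test: str | None = None
    statistic: float = np.nan
    p_value: float = np.nan
    pairwise: pd.DataFrame | None = None   # raw + adjusted pairwise p-values
    adjustment: str | None = None

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def summarize(groups: dict[str, np.ndarray]) -> list[BoxSummary]:
    """Box-plot summary per group (25/75 quartiles, 1.5×IQR whiskers)."""
    out = []
    for label, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            raise ValueError(f"group {label!r} has no finite values")
        q1, med, q3 = np.percentile(v, [25, 50, 75], method=PERCENTILE_METHOD)
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = v[(v >= lo_fence) & (v <= hi_fence)]
        out.append(BoxSummary(
            label=str(label), n=int(v.size), median=float(med),
            q1=float(q1), q3=float(q3),
            whisker_lo=float(inside.min()), whisker_hi=float(inside.max()),
            outliers=np.sort(v[(v < lo_fence) | (v > hi_fence)])))
    return out


def _dunn_sidak(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Rank-based Dunn pairwise z tests with Šidák adjustment."""
    labels = list(groups)
    vals = [np.asarray(groups[k], dtype=float) for k in labels]
    vals = [v[np.isfinite(v)] for v in vals]
    all_v = np.concatenate(vals)
    ranks = sps.rankdata(all_v)
    n_total = all_v.size
    # mean rank per group
    mean_rank, ns = [], []
    pos = 0
    for v in vals:
        mean_rank.append(ranks[pos:pos + v.size].mean())
        ns.append(v.size)
        pos += v.size
    # tie correction for the rank variance
    _, counts = np.unique(all_v, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(labels) * (len(labels) - 1) // 2
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            se = np.sqrt(var_base * (1.0 / ns[i] + 1.0 / ns[j]))
            z = (mean_rank[i] - mean_rank[j]) / se
            p_raw = 2.0 * sps.norm.sf(abs(z))
            p_adj = min(1.0, 1.0 - (1.0 - p_raw) ** m)  # Šidák
            rows.append((labels[i], labels[j], float(z), float(p_raw),
                         float(p_adj)))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "statistic",
                                       "p_raw", "p_adjusted"])


def compare(groups: dict[str, np.ndarray], test: str = "t"
            ) -> GroupComparison:
    """Compare value groups with the named test.

    ``test`` ∈ {'t', 'KS', 'ANOVA+TukeyKramer', 'KruskalWallis+DunnSidak'};
    the first two require exactly 2 groups, the omnibus tests ≥ 2.  Pairwise
    post-hoc p-values are reported raw and adjusted.
    """
    if test not in SUPPORTED_TESTS:
        raise ValueError(f"unsupported test {test!r}; supported: "
                         f"{', '.join(SUPPORTED_TESTS)}")
    summaries = summarize(groups)
    vals = [np.asarray(v, dtype=float) for v in groups.values()]
    vals = [v[np.isfinite(v)] for v in vals]

    if test in ("t", "KS"):
        if len(vals) != 2:
            raise ValueError(f"test {test!r} requires exactly 2 groups")
        if test == "t":
            res = sps.ttest_ind(vals[0], vals[1])  # two-tailed
        else:
            res = sps.ks_2samp(vals[0], vals[1])
        return GroupComparison(summaries, test, float(res.statistic),
                               float(res.pvalue))

    if len(vals) < 2:
        raise ValueError("omnibus tests require at least 2 groups")
    labels = list(groups)
    if test == "ANOVA+TukeyKramer":
        res = sps.f_oneway(*vals)
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        endog = np.concatenate(vals)
        grp = np.concatenate([[lab] * len(v) for lab, v in zip(labels, vals)])
        tk = pairwise_tukeyhsd(endog, grp)
        body = np.array(tk.summary().data[1:], dtype=object)
        pw = pd.DataFrame({
            "group_a": [str(x) for x in body[:, 0]],
            "group_b": [str(x) for x in body[:, 1]],
            "statistic": body[:, 2].astype(float),   # mean difference
            "p_raw": tk.pvalues.astype(float),
            "p_adjusted": tk.pvalues.astype(float),  # Tukey p is family-wise
        })
        return GroupComparison(summaries, test, float(res.statistic),
                               float(res.pvalue), pw, "Tukey-Kramer")
    # KruskalWallis+DunnSidak
    res = sps.kruskal(*vals)
    pw = _dunn_sidak(dict(zip(labels, vals)))
    return GroupComparison(summaries, test, float(res.statistic),
                           float(res.pvalue), pw, "Dunn-Sidak")
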