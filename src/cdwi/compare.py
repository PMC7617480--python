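"""Method comparison between acquisition schemes: Bland–Altman + Wilcoxon.

Paired per-(subject, slice) metric means from two schemes (e.g. second- vs
third-order motion compensation, or b_max 450 vs 1000 s/mm²) are compared
by Bland–Altman limits of agreement and the two-sided Wilcoxon signed-rank
test (exact null distribution up to n = 25, normal approximation with
continuity correction above; zero differences dropped, ties midranked).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PairedSummaries", "ComparisonResult", "bland_altman",
           "wilcoxon_signed_rank", "MethodComparison", "scheme_table"]


@dataclass
class PairedSummaries:
    """Index-aligned per-unit means of one metric under two schemes."""

    a: np.ndarray
    b: np.ndarray
    metric: str = ""
    label_a: str = "A"
    label_b: str = "B"
    units: np.ndarray | None = None     # e.g. (subject, slice) tags

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("paired arrays must be 1-D and index-aligned")
        if len(self.a) < 2:
            raise ValueError("need at least 2 pairs")


@dataclass
class ComparisonResult:
    """Bland–Altman and Wilcoxon summary of one paired comparison."""

    metric: str
    label_a: str
    label_b: str
    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float                # mean − 1.96 SD
    loa_high: float               # mean + 1.96 SD
    wilcoxon_stat: float
    p_value: float
    means: np.ndarray             # per-pair (a+b)/2, for plotting
    diffs: np.ndarray             # per-pair a − b

    def summary(self) -> str:
        return (
            f"{self.metric or 'metric'}: {self.label_a} vs {self.label_b} "
            f"(n={self.n})\n"
            f"  mean difference : {self.mean_diff:.4g}\n"
            f"  SD of differences: {self.sd_diff:.4g}\n"
            f"  limits of agreement: [{self.loa_low:.4g}, {self.loa_high:.4g}]\n"
            f"  Wilcoxon signed-rank: W={self.wilcoxon_stat:.4g}, "
            f"p={self.p_value:.3g}"
        )


def bland_altman(pairs: PairedSummaries) -> ComparisonResult:
    """Mean difference, SD (n−1) and ±1.96 SD limits of agreement."""
    d = pairs.a - pairs.b
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    stat, p = wilcoxon_signed_rank(pairs)
    return ComparisonResult(
        metric=pairs.metric, label_a=pairs.label_a, label_b=pairs.label_b,
        n=len(d), mean_diff=mean_d, sd_diff=sd_d,
        loa_low=mean_d - 1.96 * sd_d, loa_high=mean_d + 1.96 * sd_d,
        wilcoxon_stat=stat, p_value=p,
        means=(pairs.a + pairs.b) / 2.0, diffs=d)


def wilcoxon_signed_rank(pairs: PairedSummaries) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on the paired differences.

    Zero differences are dropped before ranking; ties get midranks.  The
    exact null distribution is used for n ≤ 25 (tie-free), the normal
    approximation with continuity correction otherwise.
    """
    d = pairs.a - pairs.b
    d = d[d != 0]
    if len(d) == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 0.0, 1.0
    ranks = np.abs(d)
    has_ties = len(np.unique(ranks)) < len(ranks)
    method = "exact" if (len(d) <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                         alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


class MethodComparison:
    """Model-style wrapper: build from per-unit summaries, ``fit()`` compares.

    ``data`` is a long-format DataFrame with columns ``scheme``, ``unit``
    (e.g. "subject3/mid") and one column per metric; ``fit`` pairs the two
    requested schemes on their common units.
    """

    def __init__(self, data: pd.DataFrame, metric: str,
                 scheme_a: str, scheme_b: str):
        for col in ("scheme", "unit", metric):
            if col not in data.columns:
                raise ValueError(f"missing column {col!r}")
        self.data = data
        self.metric = metric
        self.scheme_a = scheme_a
        self.scheme_b = scheme_b

    def fit(self) -> ComparisonResult:
        a = self.data[self.data.scheme == self.scheme_a].set_index("unit")
        b = self.data[self.data.scheme == self.scheme_b].set_index("unit")
        common = a.index.intersection(b.index)
        if len(common) < 2:
            raise ValueError("fewer than 2 common units between schemes")
        pairs = PairedSummaries(
            a=a.loc[common, self.metric].to_numpy(),
            b=b.loc[common, self.metric].to_numpy(),
            metric=self.metric, label_a=self.scheme_a,
            label_b=self.scheme_b, units=common.to_numpy())
        return bland_altman(pairs)


def scheme_table(summaries: pd.DataFrame,
                 metrics: tuple[str, ...] = ("md", "fa", "abs_e2a"),
                 schemes: tuple[str, ...] | None = None,
                 comparisons: tuple[tuple[str, str], ...] | None = None):
    """Per-scheme global mean ± SD plus pairwise difference rows.

    ``summaries`` is long-format with columns ``scheme``, ``unit`` and the
    metric columns.  Each comparison row reports Δ = mean(A − B), its SD,
    Δ% = 100·Δ/mean(B) (B the reference scheme) and the Wilcoxon p-value.
    Missing schemes produce gap rows flagged ``incomplete``.
    """
    if schemes is None:
        schemes = tuple(pd.unique(summaries.scheme))
    if comparisons is None:
        comparisons = tuple(
            (schemes[i], schemes[j])
            for i in range(len(schemes)) for j in range(i + 1, len(schemes)))
    per_scheme = []
    for sch in schemes:
        sub = summaries[summaries.scheme == sch]
        row = {"scheme": sch, "n_units": len(sub),
               "incomplete": len(sub) == 0}
        for m in metrics:
            row[f"{m}_mean"] = sub[m].mean() if len(sub) else np.nan
            row[f"{m}_sd"] = sub[m].std(ddof=1) if len(sub) > 1 else np.nan
        per_scheme.append(row)
    diff_rows = []
    for sa, sb in comparisons:
        row = {"comparison": f"{sa} vs {sb}"}
        try:
            for m in metrics:
                res = MethodComparison(summaries, m, sa, sb).fit()
                ref_mean = summaries.loc[summaries.scheme == sb, m].mean()
                row[f"d_{m}"] = res.mean_diff
                row[f"d_{m}_sd"] = res.sd_diff
                row[f"d_{m}_pct"] = (100.0 * res.mean_diff / ref_mean
                                     if ref_mean else np.nan)
                row[f"d_{m}_p"] = res.p_value
            row["incomplete"] = False
        except ValueError:
            row["incomplete"] = True
        diff_rows.append(row)
    return pd.DataFrame(per_scheme), pd.DataFrame(diff_rows)


def plot_bland_altman(result: ComparisonResult, path, slice_labels=None):
    """Bland–Altman panel: per-pair mean vs difference with mean ± 1.96 SD
    limits of agreement as solid/dashed lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    if slice_labels is not None:
        for lab in sorted(set(slice_labels)):
            sel = np.asarray(slice_labels) == lab
            ax.plot(result.means[sel], result.diffs[sel], "s", ms=4,
                    label=str(lab))
        ax.legend(fontsize=8)
    else:
        ax.plot(result.means, result.diffs, "s", ms=4)
    ax.axhline(result.mean_diff, color="k")
    ax.axhline(result.loa_low, color="k", linestyle="--")
    ax.axhline(result.loa_high, color="k", linestyle="--")
    ax.set_xlabel(f"mean of {result.label_a} and {result.label_b}")
    ax.set_ylabel(f"{result.label_a} − {result.label_b}")
    ax.set_title(result.metric)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def format_scheme_table(per_scheme: pd.DataFrame, diffs: pd.DataFrame,
                        metrics: tuple[str, ...] = ("md", "fa", "abs_e2a"),
                        pct_decimals: int = 0) -> str:
    """Human-readable report; percentages are rounded only here."""
    lines = ["Scheme summaries", "-" * 40]
    for _, r in per_scheme.iterrows():
        vals = "  ".join(
            f"{m}={r[f'{m}_mean']:.4g}±{r[f'{m}_sd']:.2g}" for m in metrics)
        lines.append(f"{r['scheme']:>12}: {vals}")
    lines += ["", "Pairwise differences", "-" * 40]
    for _, r in diffs.iterrows():
        if r.get("incomplete", False):
            lines.append(f"{r['comparison']:>20}: [missing scheme]")
            continue
        vals = "  ".join(
            f"Δ{m}={r[f'd_{m}']:.3g}±{r[f'd_{m}_sd']:.2g} "
            f"({r[f'd_{m}_pct']:.{pct_decimals}f}%, p={r[f'd_{m}_p']:.2g})"
            for m in metrics)
        lines.append(f"{r['comparison']:>20}: {vals}")
    return "\n".join(lines)
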