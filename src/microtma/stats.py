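"""Treatment-level statistics for spheroid endpoints and viability assays.

Implements the study's statistical conventions: box-plot summaries with
Tukey fences (outliers strictly more than 1.5 x IQR beyond the quartiles),
two-sided Welch t-tests against control with effects expressed as percent
change of medians, and resazurin relative-viability analysis by one-way
ANOVA with Bonferroni-adjusted pairwise t-tests versus control.

Quantiles are type-7 (linear interpolation), the default of numpy/R, stated
explicitly so hand oracles are sharp. Welch rather than Student: tumor-bearing
arms need not share variance, and the published legends say only "t test".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class TreatmentSummary:
    """Box-plot summary of one treatment arm's per-spheroid values."""

    label: str
    n: int
    median: float
    q1: float
    q3: float
    iqr: float
    lower_fence: float
    upper_fence: float
    outliers: list[float]
    whisker_low: float  # min of values within the fences
    whisker_high: float  # max of values within the fences


@dataclass
class ComparisonResult:
    """Welch t-test of a treated arm against control."""

    statistic: float
    df: float
    p_value: float
    percent_change: float | None  # 100 * (median_t - median_c) / median_c


@dataclass
class ViabilityPlate:
    """Resazurin replicate fluorescence values per dose group."""

    doses: list[str]
    values: dict[str, np.ndarray]
    control: str

    def __post_init__(self) -> None:
        if self.control not in self.doses:
            raise ValueError(f"control group {self.control!r} not among doses")
        self.values = {k: np.asarray(v, dtype=float) for k, v in self.values.items()}
        missing = [d for d in self.doses if d not in self.values]
        if missing:
            raise ValueError(f"doses without values: {missing}")


@dataclass
class ViabilityResult:
    """Per-dose relative viability and the ANOVA / post-hoc table."""

    relative_mean: dict[str, float]  # percent of control mean
    relative_sd: dict[str, float]
    anova_f: float
    anova_p: float
    anova_df: tuple[int, int]
    pairwise: dict[str, tuple[float, float, float]]  # dose -> (t, p_raw, p_adj)


def summarize(values, label: str = "") -> TreatmentSummary:
    """Box-plot statistics with Tukey fences.

    Quartiles use linear interpolation; a value is an outlier iff it lies
    strictly outside ``[Q1 - 1.5*IQR, Q3 + 1.5*IQR]``.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("summarize requires at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # type-7
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo) & (v <= hi)]
    outliers = v[(v < lo) | (v > hi)]
    return TreatmentSummary(
        label=label,
        n=int(v.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        lower_fence=float(lo),
        upper_fence=float(hi),
        outliers=sorted(float(x) for x in outliers),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
    )


def compare_to_control(treated, control) -> ComparisonResult:
    """Two-sided Welch t-test with effect size as percent change of medians."""
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    if t.size < 2 or c.size < 2:
        raise ValueError("each group needs at least 2 values")
    med_t, med_c = float(np.median(t)), float(np.median(c))
    pct = 100.0 * (med_t - med_c) / med_c if med_c != 0 else None

    if t.var(ddof=1) == 0 and c.var(ddof=1) == 0:
        if t.mean() == c.mean():
            # degenerate but unambiguous: identical constant groups
            return ComparisonResult(
                statistic=0.0, df=float(t.size + c.size - 2), p_value=1.0,
                percent_change=pct,
            )
        raise ValueError(
            "both groups have zero variance but different values; the t-test "
            "is undefined — use an exact test (e.g. Fisher/permutation)"
        )
    res = sps.ttest_ind(t, c, equal_var=False)
    return ComparisonResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        percent_change=pct,
    )


def bonferroni(p: float, n_comparisons: int) -> float:
    """Bonferroni-adjusted p-value, capped at 1."""
    return min(1.0, p * n_comparisons)


def viability_analysis(plate: ViabilityPlate) -> ViabilityResult:
    """Relative viability with one-way ANOVA and Bonferroni post-hoc tests.

    Every reading is normalised to percent of the control-group mean. The
    ANOVA runs across all dose groups with >= 2 replicates; each non-control
    group is then compared with control by Welch t-test and the p-values are
    Bonferroni-adjusted for the number of such comparisons.
    """
    ctrl = plate.values[plate.control]
    ctrl_mean = float(ctrl.mean())
    if ctrl_mean == 0:
        raise ValueError("control mean is zero; cannot normalise")
    rel = {d: 100.0 * plate.values[d] / ctrl_mean for d in plate.doses}

    testable = []
    for d in plate.doses:
        if rel[d].size >= 2:
            testable.append(d)
        else:
            warnings.warn(
                f"dose {d!r} has <2 replicates and is excluded from tests",
                stacklevel=2,
            )
    groups = [rel[d] for d in testable]
    k = len(groups)
    n_tot = sum(g.size for g in groups)
    grand = np.concatenate(groups)
    if np.ptp(grand) == 0:
        f_stat, p_anova = 0.0, 1.0  # no variance anywhere: nothing to explain
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f_stat, p_anova = sps.f_oneway(*groups)
        if not np.isfinite(f_stat):
            # zero within-group variance with distinct means: infinite evidence
            f_stat, p_anova = float("inf"), 0.0

    comparisons = [d for d in testable if d != plate.control]
    pairwise: dict[str, tuple[float, float, float]] = {}
    for d in comparisons:
        try:
            res = compare_to_control(rel[d], rel[plate.control])
        except ValueError:
            # two distinct constants: no within-group noise, treat as certain
            pairwise[d] = (float("inf"), 0.0, 0.0)
            continue
        pairwise[d] = (
            res.statistic,
            res.p_value,
            bonferroni(res.p_value, len(comparisons)),
        )
    return ViabilityResult(
        relative_mean={d: float(rel[d].mean()) for d in plate.doses},
        relative_sd={d: float(rel[d].std(ddof=1)) if rel[d].size > 1 else 0.0
                     for d in plate.doses},
        anova_f=float(f_stat),
        anova_p=float(p_anova),
        anova_df=(k - 1, n_tot - k),
        pairwise=pairwise,
    )


def boxplot_figure(groups: dict[str, np.ndarray], ylabel: str, title: str = ""):
    """Box plot in the study's convention: Tukey whiskers, open-circle outliers."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 + 0.8 * len(groups), 4.0))
    labels = list(groups)
    ax.boxplot(
        [np.asarray(groups[k], float) for k in labels],
        tick_labels=labels,
        whis=1.5,
        flierprops=dict(marker="o", markerfacecolor="none", markeredgecolor="k"),
        medianprops=dict(color="k"),
    )
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    return fig
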