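"""Cohort-level comparison of Ki-67 / Bcl-2 indices and reporting.

For every cohort pair, population, marker and strategy the index values
are compared with a normality-dependent two-group test: Student's
independent t-test when both groups pass a Shapiro–Wilk normality check
at α = 0.05, the Mann–Whitney U test otherwise.  For small groups
(both n ≤ 8) the Mann–Whitney p-value is computed by exhaustive
enumeration of all label assignments (exact even under ties); larger
groups use the normal approximation with tie and continuity
correction.  Significance stars follow the usual bands: ``*`` p < 0.05,
``**`` p < 0.01, ``***`` p < 0.001 (strict inequalities).

No multiple-testing correction is applied; the exported p-value table
states this in its footer.  Missing (QC-flagged) indices are excluded,
never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "choose_test",
    "mann_whitney",
    "student_t",
    "stars",
    "compare_indices",
    "render_report",
    "NO_CORRECTION_FOOTER",
]

NORMALITY_ALPHA = 0.05
EXACT_MAX_N = 8
NO_CORRECTION_FOOTER = "# No multiple-testing correction applied."


@dataclass
class GroupComparison:
    cohort_a: str
    cohort_b: str
    population: str
    marker: str
    strategy: str
    test: str                 # "t_test" | "mann_whitney" | "skipped"
    statistic: float
    p_value: float
    stars: str
    n_a: int
    n_b: int
    skip_reason: str = ""


def choose_test(x, y, alpha: float = NORMALITY_ALPHA) -> str:
    """``"t_test"`` iff both groups pass Shapiro–Wilk at *alpha*, else
    ``"mann_whitney"``; ``"skipped"`` for groups too small or constant."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(y) < 3:
        return "skipped"
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return "skipped"
    px = sps.shapiro(x).pvalue
    py = sps.shapiro(y).pvalue
    return "t_test" if (px >= alpha and py >= alpha) else "mann_whitney"


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann–Whitney U of x over y, with half credit for ties."""
    diff = x[:, None] - y[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test → (U statistic of x, p-value).

    Exact p by full enumeration of all ``C(n1+n2, n1)`` group splits
    when both groups have at most 8 values (the two-sided p is the
    probability of a U at least as far from its null mean as observed);
    otherwise the normal approximation with tie and continuity
    correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    u_obs = _u_statistic(x, y)
    if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        pooled = np.concatenate([x, y])
        mu = n1 * n2 / 2.0
        dev = abs(u_obs - mu) - 1e-12
        hits = 0
        total = comb(n1 + n2, n1)
        idx_all = set(range(n1 + n2))
        for pick in combinations(range(n1 + n2), n1):
            xs = pooled[list(pick)]
            ys = pooled[list(idx_all - set(pick))]
            if abs(_u_statistic(xs, ys) - mu) >= dev:
                hits += 1
        return u_obs, hits / total
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


def student_t(x, y) -> tuple[float, float]:
    """Two-sided independent two-sample Student's t-test (equal variance)."""
    res = sps.ttest_ind(np.asarray(x, float), np.asarray(y, float), equal_var=True)
    return float(res.statistic), float(res.pvalue)


def stars(p: float) -> str:
    """Significance label: ``*`` p < 0.05, ``**`` p < 0.01, ``***`` p < 0.001."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_indices(
    indices: pd.DataFrame,
    welch: bool = False,
) -> list[GroupComparison]:
    """All pairwise cohort comparisons per population × marker × strategy.

    *indices* is the long-format index table (columns ``cohort``,
    ``population``, ``marker``, ``strategy``, ``fraction``); rows with a
    missing fraction are excluded before testing.
    """
    df = indices.dropna(subset=["fraction"])
    cohorts = sorted(df["cohort"].unique())
    if len(cohorts) < 2:
        raise ValueError("need at least two cohorts with valid indices")
    out: list[GroupComparison] = []
    keys = df.groupby(["population", "marker", "strategy"], sort=True).groups
    for (pop, marker, strategy), rows in keys.items():
        sub = df.loc[rows]
        for ca, cb in combinations(cohorts, 2):
            x = sub.loc[sub["cohort"] == ca, "fraction"].to_numpy()
            y = sub.loc[sub["cohort"] == cb, "fraction"].to_numpy()
            test = choose_test(x, y)
            if test == "skipped":
                reason = (
                    "group too small" if min(len(x), len(y)) < 3 else "zero variance"
                )
                out.append(
                    GroupComparison(ca, cb, pop, marker, strategy, "skipped",
                                    np.nan, np.nan, "", len(x), len(y), reason)
                )
                continue
            if test == "t_test":
                if welch:
                    r = sps.ttest_ind(x, y, equal_var=False)
                    stat, p = float(r.statistic), float(r.pvalue)
                else:
                    stat, p = student_t(x, y)
            else:
                stat, p = mann_whitney(x, y)
            out.append(
                GroupComparison(ca, cb, pop, marker, strategy, test,
                                stat, p, stars(p), len(x), len(y))
            )
    return out


def comparisons_to_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in comparisons])


def render_report(
    comparisons: list[GroupComparison],
    indices: pd.DataFrame,
    outdir: str | Path,
    figure_format: str = "png",
) -> dict[str, Path]:
    """Write the index table, the p-value table and median+IQR figures.

    Per population × marker one panel: index values scattered by cohort
    and strategy with a median line, interquartile whiskers and the
    significance stars of the corresponding comparisons.  Returns the
    written paths.  Empty input is a no-op with a warning.
    """
    import warnings

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if indices.empty:
        warnings.warn("no indices to report", UserWarning, stacklevel=2)
        return written

    idx_path = outdir / "indices.csv"
    indices.to_csv(idx_path, index=False)
    written["indices"] = idx_path

    pcmp = comparisons_to_frame(comparisons)
    p_path = outdir / "p_values.csv"
    with open(p_path, "w") as fh:
        pcmp.to_csv(fh, index=False)
        fh.write(NO_CORRECTION_FOOTER + "\n")
    written["p_values"] = p_path

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = indices.dropna(subset=["fraction"])
    cohorts = sorted(df["cohort"].unique())
    strategies = sorted(df["strategy"].unique())

    # the summary actually drawn (median line, IQR whiskers), also exported
    summary = (
        df.groupby(["population", "marker", "strategy", "cohort"])["fraction"]
        .agg(median="median",
             q1=lambda v: float(np.percentile(v, 25)),
             q3=lambda v: float(np.percentile(v, 75)),
             n="count")
        .reset_index()
    )
    sum_path = outdir / "summary.csv"
    summary.to_csv(sum_path, index=False)
    written["summary"] = sum_path
    srows = summary.set_index(["population", "marker", "strategy", "cohort"])

    for (pop, marker), sub in df.groupby(["population", "marker"]):
        fig, axes = plt.subplots(
            1, len(strategies), figsize=(3.2 * len(strategies), 3.4), sharey=True
        )
        axes = np.atleast_1d(axes)
        for ax, strategy in zip(axes, strategies):
            ss = sub[sub["strategy"] == strategy]
            for i, cohort in enumerate(cohorts):
                vals = ss.loc[ss["cohort"] == cohort, "fraction"].to_numpy()
                if len(vals) == 0:
                    continue
                jitter = (np.arange(len(vals)) % 7 - 3) * 0.02
                ax.plot(i + jitter, vals, "o", ms=3, alpha=0.6)
                row = srows.loc[(pop, marker, strategy, cohort)]
                ax.hlines(row["median"], i - 0.25, i + 0.25, color="k", lw=2)
                ax.vlines(i, row["q1"], row["q3"], color="k", lw=1)
            y = 1.02
            for c in comparisons:
                if (
                    c.population == pop and c.marker == marker
                    and c.strategy == strategy and c.stars
                ):
                    ia, ib = cohorts.index(c.cohort_a), cohorts.index(c.cohort_b)
                    ax.annotate(
                        c.stars, ((ia + ib) / 2, y), ha="center", fontsize=9,
                        xycoords=("data", "axes fraction"),
                    )
                    y += 0.06
            ax.set_xticks(range(len(cohorts)))
            ax.set_xticklabels(cohorts, rotation=30, ha="right", fontsize=7)
            ax.set_title(strategy, fontsize=9)
        axes[0].set_ylabel(f"{marker} positive fraction")
        fig.suptitle(f"{pop}: {marker} index by gating strategy", fontsize=10)
        fig.tight_layout()
        fpath = outdir / f"index_{pop}_{marker.replace('-', '')}.{figure_format}"
        fig.savefig(fpath, dpi=120)
        plt.close(fig)
        written[f"figure_{pop}_{marker}"] = fpath
    return written
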