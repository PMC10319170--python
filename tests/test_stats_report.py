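"""Normality-dependent testing, exact Mann-Whitney, stars and reporting."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from myeloflow.stats_report import (
    NO_CORRECTION_FOOTER,
    choose_test,
    compare_indices,
    mann_whitney,
    render_report,
    stars,
)


def enumerate_mw_pvalue(x, y):
    """Independent oracle: two-sided permutation p over all group splits."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    mu = n1 * len(y) / 2.0

    def u_of(idx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        return (xs[:, None] > ys[None, :]).sum() + 0.5 * (xs[:, None] == ys[None, :]).sum()

    obs = abs(u_of(range(n1)) - mu)
    hits = sum(
        1 for pick in combinations(range(len(pooled)), n1)
        if abs(u_of(pick) - mu) >= obs - 1e-12
    )
    return hits / comb(len(pooled), n1)


class TestChooseTest:
    def test_log_skewed_goes_nonparametric(self):
        rng = np.random.default_rng(2)
        x = np.exp(rng.normal(0, 1, 25))
        y = np.exp(rng.normal(0.2, 1, 25))
        assert choose_test(x, y) == "mann_whitney"
        # agree with the reference normality check on the same draws
        assert sps.shapiro(x).pvalue < 0.05 or sps.shapiro(y).pvalue < 0.05

    def test_bell_shaped_mostly_goes_parametric(self):
        # both groups pass Shapiro-Wilk ~93% of the time at n=30, so the
        # parametric branch dominates across seeded repetitions
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            if choose_test(rng.normal(0, 1, 30), rng.normal(0, 1, 30)) == "t_test":
                hits += 1
        assert hits >= 0.85 * n_rep

    def test_constant_groups_skipped(self):
        assert choose_test([1.0] * 10, [1.0] * 10) == "skipped"

    def test_tiny_groups_skipped(self):
        assert choose_test([1.0, 2.0], [3.0, 4.0, 5.0]) == "skipped"


class TestMannWhitney:
    def test_canonical_separated_triples(self):
        _, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(2 / 20)  # both extreme splits of C(6,3)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(3, 9, size=2)
        x = rng.integers(0, 12, n1).astype(float)  # integer ties likely
        y = rng.integers(0, 12, n2).astype(float)
        _, p = mann_whitney(x, y)
        assert p == pytest.approx(enumerate_mw_pvalue(x, y), abs=1e-12)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, 7)
        y = rng.normal(1, 1, 6)
        _, p = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert p == pytest.approx(float(ref), abs=1e-12)

    def test_large_groups_use_asymptotic(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.8, 1, 40)
        _, p = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic").pvalue
        assert p == pytest.approx(float(ref))


class TestStars:
    @pytest.mark.parametrize(
        "p,label",
        [(0.03, "*"), (0.0005, "***"), (0.05, ""), (0.2, ""), (0.01, "*"),
         (0.009, "**"), (0.001, "**"), (0.0009999, "***"), (0.0, "***"), (1.0, "")],
    )
    def test_band_boundaries(self, p, label):
        assert stars(p) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stars(1.5)
        with pytest.raises(ValueError):
            stars(-0.1)

    def test_monotone_step_function(self):
        grid = np.linspace(0, 1, 401)
        ranks = [len(stars(p)) for p in grid]
        assert ranks == sorted(ranks, reverse=True)


def synthetic_indices(rng, cohorts=("A", "B", "C"), n_cases=12, shift=None):
    rows = []
    for cohort in cohorts:
        for i in range(n_cases):
            for pop in ("blast", "erythroid", "myeloid", "monocytic"):
                for marker in ("Ki-67", "Bcl-2"):
                    for strategy in ("polygon", "rectangle", "fixed40", "fixed100"):
                        base = 0.3 + (shift or {}).get(cohort, 0.0)
                        rows.append({
                            "sample_id": f"{cohort}-{i}", "cohort": cohort,
                            "population": pop, "marker": marker,
                            "strategy": strategy,
                            "fraction": float(np.clip(base + rng.normal(0, 0.05), 0, 1)),
                        })
    return pd.DataFrame(rows)


class TestCompareIndices:
    def test_identical_cohorts_not_significant(self, rng):
        df = synthetic_indices(rng, cohorts=("A", "B"))
        comps = compare_indices(df)
        assert comps
        assert all(c.stars == "" for c in comps if c.test != "skipped")

    def test_cardinality(self, rng):
        df = synthetic_indices(rng)
        comps = compare_indices(df)
        skips = sum(1 for c in comps if c.test == "skipped")
        assert len(comps) == 3 * 4 * 2 * 4  # pairs x populations x markers x strategies
        assert len(comps) - skips == sum(1 for c in comps if not np.isnan(c.p_value))

    def test_missing_indices_excluded(self, rng):
        df = synthetic_indices(rng, cohorts=("A", "B"))
        df.loc[df.index[:40], "fraction"] = np.nan
        comps = compare_indices(df)
        key = comps[0]
        assert key.n_a + key.n_b <= 24

    def test_single_cohort_rejected(self, rng):
        df = synthetic_indices(rng, cohorts=("A",))
        with pytest.raises(ValueError):
            compare_indices(df)


class TestRenderReport:
    def test_outputs_and_round_trip(self, rng, tmp_path):
        df = synthetic_indices(rng, cohorts=("A", "B"), n_cases=8)
        comps = compare_indices(df)
        written = render_report(comps, df, tmp_path / "report")
        assert "indices" in written and "p_values" in written
        back = pd.read_csv(written["indices"])
        pd.testing.assert_series_equal(back["fraction"], df["fraction"],
                                       check_names=False)
        text = written["p_values"].read_text()
        assert NO_CORRECTION_FOOTER in text
        figures = [k for k in written if k.startswith("figure_")]
        assert len(figures) == 8  # 4 populations x 2 markers

    def test_plotted_median_matches_data(self, rng, tmp_path):
        """The exported summary (the values the figure draws) agrees with an
        independently computed median/IQR of the plotted points."""
        df = synthetic_indices(rng, cohorts=("A", "B"), n_cases=6)
        written = render_report([], df, tmp_path / "r2")
        summary = pd.read_csv(written["summary"])
        sub = df[(df.population == "blast") & (df.marker == "Ki-67")
                 & (df.strategy == "polygon") & (df.cohort == "A")]["fraction"]
        row = summary[(summary.population == "blast") & (summary.marker == "Ki-67")
                      & (summary.strategy == "polygon") & (summary.cohort == "A")]
        assert row["median"].iloc[0] == pytest.approx(float(np.median(sub)))
        assert row["q1"].iloc[0] == pytest.approx(float(np.percentile(sub, 25)))
        assert row["q3"].iloc[0] == pytest.approx(float(np.percentile(sub, 75)))

    def test_empty_input_warns(self, tmp_path):
        with pytest.warns(UserWarning):
            out = render_report([], pd.DataFrame(columns=["fraction"]), tmp_path)
        assert out == {}
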