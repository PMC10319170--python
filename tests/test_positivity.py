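"""Positivity strategies, control thresholds and index computation."""

import numpy as np
import pytest

from myeloflow.fcs_io import EventTable
from myeloflow.gating import PopulationMask
from myeloflow.positivity import (
    ControlInsufficiencyError,
    PositivityConfig,
    StrategyThresholds,
    _gate_positive,
    build_strategy_gate,
    compute_all_indices,
    control_threshold,
    positive_fraction,
)
from myeloflow.synthetic_data import generate_combined, profile_from_table_row


class TestControlThreshold:
    def test_degenerate_constant_control(self):
        assert control_threshold(np.full(600, 20.0)) == 20.0

    def test_matches_sort_and_index_oracle(self):
        rng = np.random.default_rng(5)
        vals = 20 * np.exp(rng.normal(0, 0.4, 1000))
        cut = control_threshold(vals, percentile=99.5)
        expected = np.sort(vals)[int(np.ceil(0.995 * 1000)) - 1]
        assert cut == expected

    def test_too_few_events(self):
        with pytest.raises(ControlInsufficiencyError):
            control_threshold(np.ones(499))

    def test_event_table_input_uses_marker_channel(self):
        t = EventTable("s", "1", ["IgG1-FITC"], np.full((600, 1), 33.0))
        assert control_threshold(t, "IgG1-FITC") == 33.0


class TestStrategyGates:
    def test_fixed_gates_ignore_control(self):
        g40 = build_strategy_gate(999.0, "fixed40", "Ki-67-FITC")
        g100 = build_strategy_gate(1.0, "fixed100", "Ki-67-FITC")
        assert g40.geometry == (40.0, "above")
        assert g100.geometry == (100.0, "above")

    def test_flat_control_polygon_equals_rectangle(self):
        rng = np.random.default_rng(1)
        ssc = rng.uniform(0, 800, 4000)
        control = np.full(4000, 25.0)  # perfectly flat negative cloud
        cut = control_threshold(control)
        poly = build_strategy_gate(cut, "polygon", "Ki-67-FITC", "SSC-INT",
                                   population_ssc=ssc, control_marker=control,
                                   control_ssc=ssc)
        rect = build_strategy_gate(cut, "rectangle", "Ki-67-FITC", "SSC-INT")
        events = EventTable(
            "s", "1", ["SSC-INT", "Ki-67-FITC"],
            np.column_stack([rng.uniform(0, 800, 500), rng.uniform(1, 60, 500)]),
        )
        np.testing.assert_array_equal(
            _gate_positive(poly, events), _gate_positive(rect, events)
        )

    def test_rising_control_splits_hand_placed_events(self):
        """Control rising ~30 FU across SSC bins: the adaptive boundary and
        the overall rectangle disagree on exactly the two events that sit
        between the local and the global cutoff."""
        cfg = PositivityConfig(n_ssc_bins=4, min_bin_control=10)
        # four SSC bins [0,100,200,300,400]; per-bin flat controls at
        # 20/30/40/50 FU; overall 99.5th percentile = 50
        ssc = np.repeat([50.0, 150.0, 250.0, 350.0], 100)
        control = np.repeat([20.0, 30.0, 40.0, 50.0], 100)
        cut = control_threshold(control, min_events=100)
        assert cut == 50.0
        poly = build_strategy_gate(cut, "polygon", "M", "S",
                                   population_ssc=ssc, control_marker=control,
                                   control_ssc=ssc, cfg=cfg)
        rect = build_strategy_gate(cut, "rectangle", "M", "S")
        # hand-placed events: (ssc, marker)
        events = EventTable("s", "1", ["S", "M"], np.array([
            [50.0, 15.0],    # below both boundaries -> negative/negative
            [50.0, 35.0],    # above local 20, below rectangle 50 -> differs
            [150.0, 45.0],   # above local 30, below 50 -> differs
            [350.0, 55.0],   # above both -> positive/positive
            [350.0, 45.0],   # below local 50 and below 50 -> both negative
            [250.0, 75.0],   # above both -> positive/positive
        ]))
        p = _gate_positive(poly, events)
        r = _gate_positive(rect, events)
        np.testing.assert_array_equal(p, [False, True, True, True, False, True])
        np.testing.assert_array_equal(r, [False, False, False, True, False, True])
        assert int((p != r).sum()) == 2

    def test_sparse_bins_fall_back_to_rectangle(self):
        g = build_strategy_gate(40.0, "polygon", "M", "S",
                                population_ssc=np.array([1.0, 1.0, 1.0]),
                                control_marker=np.array([20.0, 20.0]),
                                control_ssc=np.array([1.0, 1.0]))
        assert g.kind == "rectangle"
        assert g.warnings  # fallback warning flag


class TestPositiveFraction:
    def _table(self, values):
        return EventTable("s", "1", ["Ki-67-FITC", "SSC-INT"],
                          np.column_stack([values, np.ones_like(values)]))

    def test_all_below_fixed40(self):
        t = self._table(np.full(500, 10.0))
        mask = PopulationMask("myeloid", np.ones(500, bool))
        gate = build_strategy_gate(0, "fixed40", "Ki-67-FITC")
        res = positive_fraction(t, mask, "Ki-67", gate)
        assert res.fraction == 0.0
        assert "insufficient_positives" in res.qc

    def test_exact_count(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(0, 100, 10_000)
        cutoff = np.sort(vals)[-1234] - 1e-9  # exactly 1234 strictly above
        t = self._table(vals)
        mask = PopulationMask("p", np.ones(10_000, bool))
        gate = build_strategy_gate(cutoff, "rectangle", "Ki-67-FITC", "SSC-INT")
        res = positive_fraction(t, mask, "Ki-67", gate)
        brute = int((vals >= cutoff).sum())
        assert res.positive == brute == 1234
        assert res.fraction == 0.1234

    def test_positive_cell_minimum_boundary(self):
        for n_pos, flagged in ((99, True), (100, False)):
            vals = np.concatenate([np.full(n_pos, 200.0), np.full(1000, 10.0)])
            t = self._table(vals)
            mask = PopulationMask("p", np.ones(len(vals), bool))
            gate = build_strategy_gate(0, "fixed40", "Ki-67-FITC")
            res = positive_fraction(t, mask, "Ki-67", gate)
            assert ("insufficient_positives" in res.qc) is flagged

    def test_empty_population_is_missing_not_zero(self):
        t = self._table(np.array([50.0]))
        mask = PopulationMask("p", np.zeros(1, bool))
        gate = build_strategy_gate(0, "fixed40", "Ki-67-FITC")
        res = positive_fraction(t, mask, "Ki-67", gate)
        assert res.fraction is None
        assert "insufficient_population" in res.qc


class TestComputeAllIndices:
    def test_thirty_two_results(self, nm_sample):
        assert len(compute_all_indices(nm_sample)) == 32

    def test_fixed100_below_fixed40(self, nm_sample):
        res = compute_all_indices(nm_sample)
        by_key = {(r.population, r.marker, r.strategy): r for r in res}
        for pop in ("blast", "erythroid", "myeloid", "monocytic"):
            for marker in ("Ki-67", "Bcl-2"):
                lo = by_key[(pop, marker, "fixed100")]
                hi = by_key[(pop, marker, "fixed40")]
                if lo.fraction is not None and hi.fraction is not None:
                    assert lo.fraction <= hi.fraction

    def test_control_anchored_recovery(self):
        """With well-separated modes, control-anchored strategies recover
        the latent blast Ki-67 fraction closely."""
        prof = profile_from_table_row("MDS", 20, n_events=35_000)  # blast-rich
        prof.true_positive_fractions = dict(prof.true_positive_fractions)
        prof.true_positive_fractions[("blast", "Ki-67")] = 0.30
        table, gt = generate_combined(prof, seed=13)
        import warnings as w

        from myeloflow.gating import gate_all
        from myeloflow.positivity import GatedSample
        with w.catch_warnings():
            w.simplefilter("ignore")
            masks = gate_all(table)
        res = compute_all_indices(GatedSample(table=table, masks=masks))
        truth = gt.true_positive_fractions[("blast", "Ki-67")]
        for r in res:
            if r.population == "blast" and r.marker == "Ki-67" and \
                    r.strategy in ("polygon", "rectangle"):
                assert r.fraction == pytest.approx(truth, abs=0.02)

    def test_raising_cutoff_never_increases_fraction(self, nm_sample):
        table = nm_sample.table
        mask = nm_sample.masks["myeloid"]
        fracs = []
        for cutoff in (20.0, 40.0, 80.0, 160.0, 320.0):
            gate = build_strategy_gate(cutoff, "rectangle", "Ki-67-FITC", "SSC-INT")
            fracs.append(positive_fraction(table, mask, "Ki-67", gate).fraction)
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_precomputed_thresholds_accepted(self, nm_sample):
        thr = StrategyThresholds(control_cutoffs={"Ki-67": 50.0, "Bcl-2": 55.0})
        res = compute_all_indices(nm_sample, thresholds=thr)
        assert len(res) == 32

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            StrategyThresholds(fixed_low=100.0, fixed_high=40.0)
        with pytest.raises(ValueError):
            StrategyThresholds(control_cutoffs={"Ki-67": -1.0})
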