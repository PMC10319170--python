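"""Hierarchical gating: debris/doublets, the four populations, invariants."""

import warnings

import numpy as np
import pytest
from scipy.stats import gaussian_kde

from myeloflow import gating
from myeloflow.gating import (
    DegenerateSeedWarning,
    EmptySampleError,
    GatingConfig,
    PopulationMask,
    count_relevant_events,
    exclude_debris_doublets,
    gate_all,
    gate_erythroid,
    gate_monocytes,
    gate_myeloid,
    population_fractions,
    positivity_threshold,
)
from myeloflow.synthetic_data import generate_combined, profile_from_table_row

from conftest import make_profile


def gated(profile, seed):
    table, gt = generate_combined(profile, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        masks = gate_all(table)
    return table, gt, masks


class TestDebrisDoublets:
    def test_clean_sample_mostly_retained(self):
        prof = make_profile(n_events=20_000, debris=0.0, doublet=0.0)
        table, _ = generate_combined(prof, seed=1)
        singlets = exclude_debris_doublets(table)
        assert singlets.count >= 0.99 * table.n_events

    def test_doublet_removal_rates(self):
        prof = make_profile(n_events=20_000, doublet=10.0, debris=0.0)
        table, gt = generate_combined(prof, seed=3)
        singlets = exclude_debris_doublets(table)
        doublet = gt.labels == "doublet"
        removed_doublets = (~singlets.mask[doublet]).mean()
        true_singlets = ~doublet
        removed_singlets = (~singlets.mask[true_singlets]).mean()
        assert removed_doublets >= 0.90
        assert removed_singlets <= 0.02

    def test_singlets_subset_of_all(self, nm_case):
        _, table, _, masks = nm_case
        assert masks["singlets"].count <= table.n_events
        assert np.all(masks["singlets"].mask | True)

    def test_missing_scatter_raises(self):
        from myeloflow.fcs_io import EventTable

        t = EventTable("s", "1", ["CD45-KO"], np.array([[1.0]]))
        with pytest.raises(KeyError):
            exclude_debris_doublets(t)


class TestRelevantEvents:
    def test_no_debris_all_relevant(self):
        prof = make_profile(n_events=10_000, debris=0.0)
        table, _ = generate_combined(prof, seed=2)
        assert count_relevant_events(table) == table.n_events

    def test_five_percent_debris(self):
        prof = make_profile(n_events=100_000, debris=5.0)
        table, gt = generate_combined(prof, seed=1)
        n_rel = count_relevant_events(table)
        assert abs(n_rel - 95_000) <= 950
        # and close to the tagged truth
        assert abs(n_rel - int(gt.relevant.sum())) <= 950

    def test_relevant_geq_singlets(self, nm_case):
        _, table, _, masks = nm_case
        assert count_relevant_events(table) >= masks["singlets"].count


class TestBlastGate:
    def test_mds_case10_recovery(self):
        prof = profile_from_table_row("MDS", 10, n_events=100_000)
        table, _, masks = (lambda p: gated(p, 21))(prof)
        rel = count_relevant_events(table)
        frac = 100.0 * masks["blast"].count / rel
        assert abs(frac - 8.5) <= 1.5

    def test_zero_blasts(self):
        prof = make_profile(n_events=50_000, blast=0.0)
        table, _, masks = gated(prof, 6)
        frac = 100.0 * masks["blast"].count / count_relevant_events(table)
        assert frac <= 0.2

    def test_precision_recall(self):
        prof = make_profile(n_events=100_000, blast=10.0)
        table, gt, masks = gated(prof, 11)
        pred = masks["blast"].mask
        truth = gt.labels == "blast"
        tp = (pred & truth).sum()
        precision = tp / max(pred.sum(), 1)
        recall = tp / truth.sum()
        assert precision >= 0.9 and recall >= 0.9


class TestErythroidGate:
    def test_nm_case2_recovery(self):
        prof = profile_from_table_row("non_malignant", 2, n_events=100_000)
        table, _, masks = gated(prof, 22)
        frac = 100.0 * masks["erythroid"].count / count_relevant_events(table)
        assert abs(frac - 19.3) <= 2.0

    def test_platelet_step_without_platelets(self):
        prof = make_profile(n_events=30_000, platelet=0.0)
        table, _ = generate_combined(prof, seed=8)
        singlets = exclude_debris_doublets(table)
        ery = gate_erythroid(table, singlets)
        chain = {node.name: node for node in ery.chain()}
        pre = chain["minus_lymphoid"].count
        post = chain["minus_platelets"].count
        assert pre - post <= 0.005 * max(pre, 1)

    def test_containment_chain(self, nm_case):
        _, table, _, masks = nm_case
        chain = masks["erythroid"].chain()
        for parent, child in zip(chain, chain[1:]):
            assert not np.any(child.mask & ~parent.mask)


class TestMyeloidGate:
    def test_nm_case9_recovery(self):
        prof = profile_from_table_row("non_malignant", 9, n_events=100_000)
        table, _, masks = gated(prof, 23)
        frac = 100.0 * masks["myeloid"].count / count_relevant_events(table)
        assert abs(frac - 83.8) <= 3.0

    def test_eosinophil_exclusion(self):
        prof = make_profile(n_events=50_000, eosinophil=3.0)
        table, gt, _ = gated(prof, 9)
        singlets = exclude_debris_doublets(table)
        mye = gate_myeloid(table, singlets)
        chain = {node.name: node for node in mye.chain()}
        candidates = chain["minus_mature_monocytes"].mask
        eos_in = gt.labels == "eosinophil"
        eligible = candidates & eos_in
        if eligible.sum():
            kept = (mye.mask & eos_in).sum() / eligible.sum()
            assert kept <= 0.2

    def test_disjoint_from_monocytes(self, nm_case):
        _, _, _, masks = nm_case
        assert not np.any(masks["myeloid"].mask & masks["monocytic"].mask)


class TestMonocyteGate:
    def test_aml_case24_recovery(self):
        prof = profile_from_table_row("AML", 24, n_events=100_000)
        table, _, masks = gated(prof, 24)
        frac = 100.0 * masks["monocytic"].count / count_relevant_events(table)
        assert abs(frac - 35.4) <= 3.0

    def test_zero_monocytes_warns_and_near_empty(self):
        prof = make_profile(n_events=30_000, monocytic=0.0, blast=1.0,
                            erythroid=18.0, myeloid=55.0)
        table, _ = generate_combined(prof, seed=10)
        singlets = exclude_debris_doublets(table)
        with pytest.warns(DegenerateSeedWarning):
            mono = gate_monocytes(table, singlets)
        frac = 100.0 * mono.count / count_relevant_events(table)
        assert frac <= 0.5

    def test_monotone_in_configured_fraction(self):
        recovered = []
        for target in (2.0, 10.0, 30.0):
            prof = make_profile(n_events=30_000, monocytic=target, myeloid=35.0)
            table, _, masks = gated(prof, 12)
            recovered.append(masks["monocytic"].count / count_relevant_events(table))
        assert recovered[0] <= recovered[1] <= recovered[2]


class TestPopulationFractions:
    def test_zero_counts_zero_fractions(self):
        masks = {
            p: PopulationMask(p, np.zeros(10, bool))
            for p in ("blast", "erythroid", "myeloid", "monocytic")
        }
        fr = population_fractions(masks, 10)
        assert all(v == 0.0 for v in fr.fractions.values())

    def test_printed_row_arithmetic(self):
        n = 100_000
        counts = {"blast": 300, "erythroid": 9400, "myeloid": 63600, "monocytic": 600}
        masks = {}
        start = 0
        for pop, c in counts.items():
            m = np.zeros(n, bool)
            m[start : start + c] = True
            start += c
            masks[pop] = PopulationMask(pop, m)
        fr = population_fractions(masks, n)
        assert fr.rounded() == {
            "blast": 0.3, "erythroid": 9.4, "myeloid": 63.6, "monocytic": 0.6
        }

    def test_empty_sample_error(self):
        masks = {p: PopulationMask(p, np.zeros(0, bool))
                 for p in ("blast", "erythroid", "myeloid", "monocytic")}
        with pytest.raises(EmptySampleError):
            population_fractions(masks, 0)

    def test_permutation_invariance(self, nm_case, rng):
        _, table, _, masks = nm_case
        rel = count_relevant_events(table)
        fr = population_fractions(masks, rel)
        perm = rng.permutation(table.n_events)
        permuted = {
            p: PopulationMask(p, masks[p].mask[perm])
            for p in ("blast", "erythroid", "myeloid", "monocytic")
        }
        assert population_fractions(permuted, rel).fractions == fr.fractions


class TestInvariants:
    def test_final_masks_pairwise_disjoint(self, nm_case):
        _, _, _, masks = nm_case
        pops = ["blast", "erythroid", "myeloid", "monocytic"]
        for i, a in enumerate(pops):
            for b in pops[i + 1:]:
                assert not np.any(masks[a].mask & masks[b].mask), (a, b)

    def test_population_masks_contained_in_singlets(self, nm_case):
        _, _, _, masks = nm_case
        s = masks["singlets"].mask
        for p in ("blast", "erythroid", "myeloid", "monocytic"):
            assert not np.any(masks[p].mask & ~s)

    def test_containment_survives_config_changes(self):
        prof = make_profile(n_events=10_000)
        table, _ = generate_combined(prof, seed=14)
        cfg = GatingConfig(doublet_mad_k=2.0, mono_box_pad=0.4,
                           eosinophil_tail_q=0.99)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            masks = gate_all(table, cfg)
        s = masks["singlets"].mask
        pops = ["blast", "erythroid", "myeloid", "monocytic"]
        for p in pops:
            assert not np.any(masks[p].mask & ~s)
        for i, a in enumerate(pops):
            for b in pops[i + 1:]:
                assert not np.any(masks[a].mask & masks[b].mask)


class TestDensityValley:
    def test_threshold_matches_grid_search_oracle(self, rng):
        """The valley finder equals an exhaustive argmin of the same
        smoothed log-density between the outer modes."""
        x = np.concatenate([
            20 * np.exp(rng.normal(0, 0.3, 4000)),
            400 * np.exp(rng.normal(0, 0.3, 1500)),
        ])
        thr = positivity_threshold(x)

        # independent oracle: full-resolution KDE grid scan
        logs = np.sort(np.log10(x))
        kde = gaussian_kde(logs, bw_method="silverman")
        grid = np.linspace(logs[0] - 0.05, logs[-1] + 0.05, 512)
        dens = kde(grid)
        peaks = [
            i for i in range(1, 511) if dens[i] > dens[i - 1] and dens[i] >= dens[i + 1]
        ]
        lo_pk, hi_pk = peaks[0], peaks[-1]
        between = slice(lo_pk + 1, hi_pk)
        oracle = 10 ** grid[between][np.argmin(dens[between])]
        assert thr == pytest.approx(oracle, rel=0.02)

    def test_unimodal_falls_back(self, rng):
        x = 20 * np.exp(rng.normal(0, 0.3, 3000))
        assert positivity_threshold(x, fallback=123.0) == 123.0

    def test_degenerate_all_equal(self):
        x = np.full(1000, 20.0)
        assert positivity_threshold(x, fallback=77.0) == 77.0
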