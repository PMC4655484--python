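import math

import numpy as np
import pytest

import paleoshift as ps
from paleoshift import chrono, paleorates, synthdata
from paleoshift.synthdata import (
    EmptyFossilRecordError,
    ExtinctionPulse,
    RateShift,
    ScenarioSpec,
    TotalExtinctionError,
)


class TestSimulateBdTree:
    def test_pure_birth_all_tips_extant(self):
        spec = ScenarioSpec(lam=0.2, mu=0.0, window=(310, 300), seed=1)
        sim = synthdata.simulate_bd_tree(spec)
        assert all(t.lad == 300 for t in sim.ctree.ranges.values())
        assert sim.extant == set(sim.ctree.ranges)

    def test_yule_expected_tip_count(self):
        # E[N] = 2 e^{lambda T} = 2 e^3 for lambda = 0.3 over 10 Ma
        total = 0
        reps = 300
        rng = np.random.default_rng(7)
        spec = ScenarioSpec(lam=0.3, mu=0.0, window=(310, 300))
        for _ in range(reps):
            total += synthdata.simulate_bd_tree(spec, rng).ctree.n_tips()
        mean = total / reps
        expected = 2 * math.exp(3.0)
        # per-replicate sd of a two-lineage Yule count, three standard errors
        sd = math.sqrt(2 * math.exp(3) * (math.exp(3) - 1))
        assert abs(mean - expected) < 3 * sd / math.sqrt(reps)

    def test_shifted_clade_outgrows_sister(self):
        sizes, sisters = [], []
        rng = np.random.default_rng(11)
        spec = ScenarioSpec(
            lam=0.1, mu=0.02, window=(320, 270),
            shifts=(RateShift(age=280.0, new_lam=0.5, new_mu=0.02),),
            max_tips=3000,
        )
        for _ in range(30):
            try:
                sim = synthdata.simulate_bd_tree(spec, rng)
            except (TotalExtinctionError, synthdata.TreeTooLargeError):
                continue
            if not sim.shift_clades:
                continue
            clade = sim.shift_clades[0]
            node = None
            for n in sim.ctree.tree.preorder_node_iter():
                if frozenset(l.taxon.label for l in n.leaf_iter()) == clade:
                    node = n
                    break
            if node is None or node.parent_node is None:
                continue
            sib = [c for c in node.parent_node.child_nodes() if c is not node][0]
            sizes.append(len(clade))
            sisters.append(len(sib.leaf_nodes()))
        assert len(sizes) >= 10
        assert np.mean(sizes) > np.mean(sisters)

    def test_total_extinction_flagged(self):
        spec = ScenarioSpec(lam=0.0, mu=2.0, window=(310, 300), seed=0)
        with pytest.raises(TotalExtinctionError):
            synthdata.simulate_bd_tree(spec)
        sim = synthdata.simulate_bd_tree(spec, require_survival=False)
        assert sim.extant == set()

    def test_trait_dependent_pulse_survival(self):
        # trait-positive lineages survive the lottery preferentially
        rng = np.random.default_rng(3)
        spec = ScenarioSpec(
            lam=0.15, mu=0.0, window=(320, 280),
            pulses=(ExtinctionPulse(age=300.0, survival=(0.1, 0.9)),),
            q01=0.05, q10=0.05,
        )
        pos = neg = 0
        for _ in range(20):
            try:
                sim = synthdata.simulate_bd_tree(spec, rng)
            except TotalExtinctionError:
                continue
            for name in sim.extant:
                if sim.tip_states[name] == 1:
                    pos += 1
                else:
                    neg += 1
        assert pos > neg

    def test_round_trip_through_calibrate(self):
        sim = synthdata.simulate_bd_tree(
            ScenarioSpec(lam=0.15, mu=0.05, window=(320, 290), seed=5),
            require_survival=False,
        )
        recal = chrono.calibrate(sim.ctree.tree, sim.ctree.ranges, min_branch=0)
        # fad-based calibration places a node at its oldest descendant
        # first appearance, which can only compress true ages (a node whose
        # children are both internal has no tip reaching back to its split)
        true_by_clade = {
            frozenset(l.taxon.label for l in n.leaf_iter()): n.age
            for n in sim.ctree.tree.preorder_internal_node_iter()
        }
        for n in recal.tree.preorder_internal_node_iter():
            clade = frozenset(l.taxon.label for l in n.leaf_iter())
            assert n.age <= true_by_clade[clade] + 1e-9
            kids = n.child_nodes()
            if any(k.is_leaf() for k in kids):
                # a leaf child's fad equals the true split age
                assert n.age == pytest.approx(true_by_clade[clade])


class TestTraitHistory:
    def test_zero_rates_freeze_root_state(self, five_tip_ctree):
        node_states, tip_states = ps.simulate_trait_history(
            five_tip_ctree, 0.0, 0.0, seed=1
        )
        assert set(tip_states.values()) == {0}
        assert set(node_states.values()) == {0}

    def test_high_rates_approach_stationary_frequencies(self):
        sim = synthdata.simulate_bd_tree(
            ScenarioSpec(lam=0.1, mu=0.02, window=(320, 270), seed=2, max_tips=1000)
        )
        assert sim.ctree.n_tips() >= 40
        _, tip_states = ps.simulate_trait_history(sim.ctree, 2.0, 1.0, seed=3)
        freq1 = np.mean(list(tip_states.values()))
        assert abs(freq1 - 2 / 3) < 0.1

    def test_deterministic_under_seed(self, five_tip_ctree):
        a = ps.simulate_trait_history(five_tip_ctree, 0.05, 0.02, seed=9)
        b = ps.simulate_trait_history(five_tip_ctree, 0.05, 0.02, seed=9)
        assert a == b


class TestFossilSampling:
    def sim(self, seed=4):
        return synthdata.simulate_bd_tree(
            ScenarioSpec(lam=0.15, mu=0.06, window=(320, 280), seed=seed),
            require_survival=False,
        )

    def test_dense_sampling_recovers_true_ranges(self):
        sim = self.sim()
        topo, ranges = ps.simulate_fossil_sampling(sim, r=60.0, seed=1)
        assert set(ranges) == set(sim.ctree.ranges)
        for leaf in sim.ctree.tree.leaf_node_iter():
            name = leaf.taxon.label
            origin = sim.ctree.branch_origin(leaf)
            assert ranges[name].fad == pytest.approx(origin, abs=0.5)
            assert ranges[name].lad == pytest.approx(
                sim.ctree.ranges[name].lad, abs=0.5
            )

    def test_zero_rate_flagged_empty(self):
        with pytest.raises(EmptyFossilRecordError):
            ps.simulate_fossil_sampling(
                self.sim(), r=0.0, seed=1, observe_extant_at_close=False
            )

    def test_extant_lineages_observed_at_close(self):
        sim = self.sim()
        _, ranges = ps.simulate_fossil_sampling(sim, r=0.0, seed=1)
        assert set(ranges) == sim.extant
        assert all(t.lad == 280 for t in ranges.values())

    def test_sparser_sampling_lowers_sampling_proportion(self):
        diffs = []
        ts = ps.TimeScale(
            [ps.TimeScaleBin(f"b{i}", 320 - 5 * i, 315 - 5 * i) for i in range(8)]
        )
        for seed in range(15):
            sim = self.sim(seed)
            out = {}
            for r in (0.2, 1.5):
                try:
                    topo, ranges = ps.simulate_fossil_sampling(sim, r, seed=seed)
                except EmptyFossilRecordError:
                    break
                if len(ranges) < 3:
                    break
                ct = chrono.calibrate(topo, ranges, min_branch=0)
                out[r] = float(np.mean(paleorates.sampling_proportion(ct, ts)))
            if len(out) == 2:
                diffs.append(out[1.5] - out[0.2])
        assert len(diffs) >= 8
        assert np.mean(diffs) > 0


class TestScenarioGenerator:
    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="preset"):
            synthdata.scenario_generator("nope", 1)

    def test_bundle_files_round_trip(self, tmp_path):
        bundle = synthdata.scenario_generator("erm-null", 7, out_dir=tmp_path)
        topo, ranges, traits, stages = synthdata.load_bundle_inputs(tmp_path)
        assert sorted(l.taxon.label for l in topo.leaf_node_iter()) == sorted(ranges)
        assert set(traits) == set(ranges)
        for name, taxon in bundle.ranges.items():
            assert ranges[name].fad == pytest.approx(taxon.fad)
            assert ranges[name].lad == pytest.approx(taxon.lad)
        ct = chrono.calibrate(topo, ranges, min_branch=1.0)
        assert ct.n_tips() == len(ranges)

    def test_same_seed_byte_identical(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        synthdata.scenario_generator("clade-shift", 3, out_dir=d1)
        synthdata.scenario_generator("clade-shift", 3, out_dir=d2)
        for name in ("tree.nwk", "ranges.csv", "traits.csv", "stages.csv", "manifest.txt"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_manifest_records_truth(self):
        bundle = synthdata.scenario_generator("clade-shift", 2)
        m = bundle.manifest
        assert m["preset"] == "clade-shift"
        assert m["shift0_lambda"] == pytest.approx(0.5)
        assert m["n_tips_observed"] == len(bundle.ranges)

    def test_pulse_preset_respects_size_conditioning(self):
        bundle = synthdata.scenario_generator("trait-buffered-pulse", 4)
        assert 60 <= bundle.manifest["n_tips_true"] <= 500
        assert "pulse0_age" in bundle.manifest
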