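"""1D lattice engine: motor dynamics, occupancy, loading, synapsis rules."""

import numpy as np
import pytest
from scipy import stats as sps

from loopsynapse import _kernels as K
from loopsynapse.config import SimConfig
from loopsynapse.lattice import LatticeSimulation, run_simulation
from loopsynapse.theory import expected_dsb_loading_fraction

HUGE = 1e15  # effectively infinite processivity


def occupancy_check(sim):
    """Recount motors per site and compare against the packed bookkeeping."""
    G = sim.config.genome_length_kb
    cnt = np.zeros(G, dtype=int)
    np.add.at(cnt, sim.left, 1)
    np.add.at(cnt, sim.right, 1)
    assert (cnt == (sim.pack & 4095)).all()
    normal = (sim.flags & (K.F_BE | K.F_END)) == 0
    be = (sim.flags & K.F_BE) > 0
    assert cnt[be].max(initial=0) <= 1
    free = int((normal & (cnt == 0)).sum())
    assert free == sim.meta[K.META_FREE]
    assert sim.meta[K.META_OVERFLOW] == 0 and sim.meta[K.META_LOADFAIL] == 0
    assert (sim.left <= sim.right).all()


def manual_sim(G, lefs, dsb_e, lam=HUGE, **cfg_over):
    """Build a frozen simulation with hand-placed LEFs around one DSB site.

    All motors are stall-latched so that a single step only runs the
    synapsis monitor; with infinite processivity no LEF unbinds.
    """
    over = dict(genome_length_kb=G, lef_separation_kb=G // len(lefs),
                lef_processivity_kb=lam, be_spacing_range_kb=(G, G),
                boundary_strength=0.0, dsb_spacing_kb=G, burnin_steps=0)
    over.update(cfg_over)
    sim = LatticeSimulation(SimConfig(**over), seed=0)
    assert sim.n_lefs == len(lefs)
    sim.pack[:] = 0
    for l, (a, b) in enumerate(lefs):
        sim.left[l], sim.right[l] = a, b
        for s in (a, b):
            sim.pack[s] = (l << 12) | ((sim.pack[s] & 4095) + 1)
        sim.stall_l[l] = 1
        sim.stall_r[l] = 1
    normal = (sim.flags & (K.F_BE | K.F_END)) == 0
    sim.meta[K.META_FREE] = int((normal & ((sim.pack & 4095) == 0)).sum())
    sim.dsb_left[0] = dsb_e
    return sim


class TestMotorDynamics:
    def test_lone_lef_extrudes_symmetrically(self):
        sim = manual_sim(1000, [(500, 500)], 100)
        sim.stall_l[:] = 0
        sim.stall_r[:] = 0
        for t in range(1, 11):
            sim.step(1, monitor=False)
            assert (sim.left[0], sim.right[0]) == (500 - t, 500 + t)

    def test_certain_boundary_stalls_latch_permanently(self):
        cfg = SimConfig(genome_length_kb=1500, be_spacing_range_kb=(500, 500),
                        lef_separation_kb=1500, lef_processivity_kb=HUGE,
                        boundary_strength=1.0, burnin_steps=0, dsb_spacing_kb=1500)
        sim = LatticeSimulation(cfg, seed=4)
        sim.step(3000, monitor=False)
        # b=1: every motor that meets a convergent BE latches there for good
        assert sim.stall_l[0] or sim.stall_r[0]
        state = (sim.left[0], sim.right[0], sim.stall_l[0], sim.stall_r[0])
        frozen_l, frozen_r = bool(sim.stall_l[0]), bool(sim.stall_r[0])
        sim.step(100, monitor=False)
        if frozen_l:
            assert sim.left[0] == state[0] and sim.stall_l[0]
        if frozen_r:
            assert sim.right[0] == state[1] and sim.stall_r[0]

    def test_motors_never_cross_broken_dsb_ends(self):
        cfg = SimConfig(genome_length_kb=20_000, lef_separation_kb=100,
                        lef_processivity_kb=400, boundary_strength=0.0,
                        dsb_spacing_kb=5000, burnin_steps=500,
                        targeted_loading_fold=500.0, max_post_dsb_steps=100)
        sim = LatticeSimulation(cfg, seed=5)
        sim.step(cfg.burnin_steps, monitor=False)
        sim.introduce_dsbs()
        spanning_at_break = {l for k in range(len(sim.dsb_left))
                             for l in sim.cons[k, : sim.cons_n[k]]}
        for _ in range(20):
            sim.step(50)
            occupancy_check(sim)
            for k, e in enumerate(sim.dsb_left):
                spans = np.flatnonzero((sim.left <= e) & (sim.right >= e + 1))
                assert set(spans) <= spanning_at_break

    def test_occupancy_invariants_through_dense_dynamics(self):
        cfg = SimConfig(genome_length_kb=20_000, lef_separation_kb=100,
                        lef_processivity_kb=200, be_stabilization_fold=4.0,
                        dsb_spacing_kb=5000, burnin_steps=0,
                        targeted_loading_fold=1000.0, max_post_dsb_steps=5000)
        sim = LatticeSimulation(cfg, seed=7)
        for _ in range(10):
            sim.step(100, monitor=False)
            occupancy_check(sim)
        sim.introduce_dsbs()
        for _ in range(20):
            sim.step(100)
            occupancy_check(sim)

    def test_lef_count_conserved(self):
        cfg = SimConfig(genome_length_kb=50_000, lef_separation_kb=250,
                        lef_processivity_kb=300, burnin_steps=0)
        sim = LatticeSimulation(cfg, seed=1)
        assert sim.n_lefs == 200
        sim.step(2000, monitor=False)
        assert (sim.left >= 0).all() and len(sim.left) == 200


class TestLoading:
    def test_steady_state_positions_uniform_without_boundaries(self):
        cfg = SimConfig(genome_length_kb=50_000, lef_separation_kb=250,
                        lef_processivity_kb=300, boundary_strength=0.0,
                        burnin_steps=3000)
        sim = LatticeSimulation(cfg, seed=2)
        sim.step(cfg.burnin_steps, monitor=False)
        counts = np.zeros(10)
        for _ in range(30):
            sim.step(300, monitor=False)
            pos = np.concatenate([sim.left, sim.right])
            counts += np.bincount(pos // 5000, minlength=10)
        assert sps.chisquare(counts).pvalue > 1e-3

    def test_unbinding_rate_matches_processivity(self):
        # unobstructed LEFs unbind with probability 2/lambda per step
        lam = 200.0
        cfg = SimConfig(genome_length_kb=100_000, lef_separation_kb=1000,
                        lef_processivity_kb=lam, boundary_strength=0.0,
                        burnin_steps=500)
        sim = LatticeSimulation(cfg, seed=3)
        sim.step(500, monitor=False)
        sim.reset_loading_counters()
        n_steps = 4000
        sim.step(n_steps, monitor=False)
        events = sim.meta[K.META_LOADS]
        expected = sim.n_lefs * n_steps * 2.0 / lam
        assert abs(events - expected) < 4 * np.sqrt(expected)

    def test_infinite_processivity_never_unbinds(self):
        sim = manual_sim(2000, [(1000, 1000)], 100)
        sim.stall_l[:] = 0
        sim.stall_r[:] = 0
        sim.reset_loading_counters()
        sim.step(2000, monitor=False)
        assert sim.meta[K.META_LOADS] == 0

    def test_targeted_loading_fraction_matches_weighting(self):
        F = 1000.0
        cfg = SimConfig(genome_length_kb=100_000, lef_separation_kb=125,
                        lef_processivity_kb=300, dsb_spacing_kb=10_000,
                        targeted_loading_fold=F, burnin_steps=3000,
                        max_post_dsb_steps=100)
        sim = LatticeSimulation(cfg, seed=6)
        sim.step(cfg.burnin_steps, monitor=False)
        sim.introduce_dsbs()
        sim.reset_loading_counters()
        sim.step(2000, monitor=False)
        n_dsb = len(sim.dsb_left)
        frac = sim.meta[K.META_LOADS_END] / sim.meta[K.META_LOADS]
        G = cfg.genome_length_kb
        expected = 2 * n_dsb * F / (2 * n_dsb * F + G - 2 * n_dsb)
        sigma = np.sqrt(expected * (1 - expected) / sim.meta[K.META_LOADS])
        # free-site weighting biases the tally up by at most the occupied fraction
        assert abs(frac - expected) < 4 * sigma + expected * 0.02


class TestSynapsisRules:
    def run_monitor(self, sim):
        sim.introduce_dsbs()
        sim.step(1)
        return sim

    def test_motors_on_both_end_sites_is_success(self):
        sim = self.run_monitor(manual_sim(1000, [(100, 101)], 100))
        assert sim.dsb_state[0] == 1

    def test_small_gaps_both_sides_success(self):
        # gaps (2, 0)
        sim = self.run_monitor(manual_sim(1000, [(97, 102)], 100))
        assert sim.dsb_state[0] == 1

    def test_three_site_gap_not_synapsed(self):
        # gaps (3, 1): monitoring continues
        sim = self.run_monitor(manual_sim(1000, [(96, 103)], 100))
        assert sim.dsb_state[0] == 0

    def test_gap_bridging_subloop_counts_as_extruded(self):
        # constraining loop leaves a 9-site gap; a sub-loop anchored at the
        # end site extrudes all but 2 of it
        bare = self.run_monitor(manual_sim(1000, [(90, 102)], 100))
        assert bare.dsb_state[0] == 0
        bridged = self.run_monitor(manual_sim(1000, [(90, 102), (93, 100)], 100))
        assert bridged.dsb_state[0] == 1

    def test_unconstrained_dsb_fails_immediately(self):
        sim = manual_sim(1000, [(300, 400)], 100)
        sim.introduce_dsbs()
        assert sim.dsb_state[0] == 2
        assert sim.dsb_time[0] == 0
        out = sim.finalize_outcomes()
        assert not out["constrained"][0] and out["result"][0] == "failure"

    def test_unresolved_dsb_censored_at_cap(self):
        sim = manual_sim(1000, [(50, 150)], 100, max_post_dsb_steps=200)
        sim.introduce_dsbs()
        sim.step(200)
        out = sim.finalize_outcomes()
        assert out["result"][0] == "censored"
        assert out["time_steps"][0] == 200

    def test_failure_when_last_constraining_lef_unbinds(self):
        # lambda = 2 kb: the constraining LEF unbinds almost immediately
        sim = manual_sim(1000, [(50, 150)], 100, lam=2.0)
        sim.introduce_dsbs()
        sim.step(500)
        out = sim.finalize_outcomes()
        assert out["result"][0] == "failure"
        assert out["constrained"][0]


class TestRunSimulation:
    def test_deterministic_under_fixed_seed(self):
        cfg = SimConfig(genome_length_kb=50_000, burnin_steps=1000,
                        max_post_dsb_steps=20_000, seed=11)
        a = run_simulation(cfg)
        b = run_simulation(cfg)
        assert a.outcomes.equals(b.outcomes)
        c = run_simulation(cfg, seed=12)
        assert not a.outcomes.equals(c.outcomes)

    def test_single_immortal_spanning_lef_holds_dsb_constrained(self):
        # one LEF, no boundaries, infinite processivity: it spans the DSB and
        # never unbinds, so the DSB stays constrained; with no other LEF to
        # bridge the gaps the attempt can only end by censoring
        cfg = SimConfig(genome_length_kb=2000, lef_separation_kb=2000,
                        lef_processivity_kb=HUGE, boundary_strength=0.0,
                        be_spacing_range_kb=(2000, 2000), dsb_spacing_kb=2000,
                        burnin_steps=3000, max_post_dsb_steps=5_000, seed=13)
        res = run_simulation(cfg)
        assert len(res.outcomes) == 1
        assert bool(res.outcomes["constrained"][0])
        assert res.outcomes["result"][0] == "censored"

    def test_lef_population_with_targeted_loading_bridges_reliably(self):
        # many LEFs plus strong targeted loading: every constrained DSB is
        # bridged well before the cap
        cfg = SimConfig(genome_length_kb=30_000, lef_separation_kb=125,
                        lef_processivity_kb=250, boundary_strength=0.5,
                        be_stabilization_fold=16.0, longlived_fraction=0.2,
                        dsb_stabilization_fold=2.0, targeted_loading_fold=1000.0,
                        dsb_spacing_kb=10_000, burnin_steps=20_000,
                        max_post_dsb_steps=100_000, seed=13)
        res = run_simulation(cfg)
        constrained = res.outcomes["constrained"]
        assert constrained.any()
        assert (res.outcomes.loc[constrained, "result"] != "censored").all()

    def test_invalid_config_rejected_before_stepping(self):
        with pytest.raises(ValueError):
            SimConfig(lef_processivity_kb=0)
        with pytest.raises(ValueError):
            SimConfig(boundary_strength=1.5)
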