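"""Analytical layer: coverage, timescales, synapsis probability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from loopsynapse.config import SimConfig
from loopsynapse.lattice import LatticeSimulation, loop_coverage_from_snapshot
from loopsynapse.theory import (
    TheoryParams,
    Timescales,
    compute_timescales,
    expected_dsb_loading_fraction,
    loop_coverage,
    mean_loop_length,
    p_end_joining_given_constrained,
    p_synapsis,
)


class TestLoopCoverage:
    def test_vanishes_as_processivity_ratio_vanishes(self):
        assert loop_coverage(TheoryParams(lam=1e-3, d=500.0)) < 1e-5

    def test_saturates_as_processivity_ratio_diverges(self):
        assert loop_coverage(TheoryParams(lam=np.inf, d=125.0)) == 1.0
        assert loop_coverage(TheoryParams(lam=1e9, d=125.0)) > 0.95

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            TheoryParams(lam=0.0, d=125.0)
        with pytest.raises(ValueError):
            TheoryParams(lam=300.0, d=-1.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(lam=st.floats(10, 3000), d=st.floats(50, 1000),
           b=st.floats(0, 1), w=st.floats(1, 32), a0=st.floats(0, 0.5))
    def test_probability_bounds_and_ordering(self, lam, d, b, w, a0):
        p = TheoryParams(lam=lam, d=d, b=b, w=w, alpha0=a0)
        cov = loop_coverage(p)
        ps = p_synapsis(p)
        assert 0.0 <= cov <= 1.0
        assert 0.0 <= ps <= cov + 1e-12

    def test_collision_free_limit_matches_brute_force_on_toy_genome(self):
        """b=0, no stabilization: coverage vs a 5-Mb lattice estimate.

        Measured away from the chromosome ends (a boundary layer of ~2
        processivity lengths), where the bulk steady state applies.
        """
        lam, d, G = 100, 80, 5000
        covs = []
        for seed in (1, 2, 3, 4):
            cfg = SimConfig(genome_length_kb=G, lef_separation_kb=d,
                            lef_processivity_kb=lam, boundary_strength=0.0,
                            burnin_steps=2000, seed=seed)
            sim = LatticeSimulation(cfg)
            sim.step(cfg.burnin_steps, monitor=False)
            for _ in range(50):
                sim.step(100, monitor=False)
                lo, hi = 2 * lam, G - 2 * lam
                cov = np.zeros(hi - lo, dtype=bool)
                keep = sim.right > sim.left + 1
                for a, b in zip(sim.left[keep] + 1, sim.right[keep]):
                    a, b = max(a, lo), min(b, hi)
                    if b > a:
                        cov[a - lo:b - lo] = True
                covs.append(cov.mean())
        theory = loop_coverage(TheoryParams(lam=lam, d=d, b=0.0))
        assert abs(np.mean(covs) - theory) < 0.02


class TestTimescales:
    def test_weighted_ratios_reduce_to_plain_without_mechanisms(self):
        ts = compute_timescales(TheoryParams(lam=300, d=240, b=0.5, F=500))
        assert ts.weighted_ratio_loading == pytest.approx(ts.ratio_loading)
        assert ts.weighted_ratio_extrusion == pytest.approx(ts.ratio_extrusion)

    def test_doubling_be_stabilization_doubles_latched_residence(self):
        p2 = TheoryParams(lam=300, d=240, b=0.5, w=2)
        p4 = TheoryParams(lam=300, d=240, b=0.5, w=4)
        t2 = compute_timescales(p2, constraining_at_be=True)
        t4 = compute_timescales(p4, constraining_at_be=True)
        assert t4.tau_constrained == pytest.approx(2 * t2.tau_constrained)
        # tau_loading moves only marginally with w, so the ratio ~halves
        assert t4.weighted_ratio_loading == pytest.approx(t2.weighted_ratio_loading / 2, rel=1e-2)

    def test_zero_gap_means_zero_extrusion_time(self):
        ts = compute_timescales(TheoryParams(), gap_kb=0.0)
        assert ts.tau_extrusion == 0.0

    def test_targeted_loading_shortens_loading_time(self):
        slow = compute_timescales(TheoryParams(F=1), gap_kb=100.0)
        fast = compute_timescales(TheoryParams(F=1000), gap_kb=100.0)
        assert fast.tau_loading < slow.tau_loading


class TestEndJoiningProbability:
    def mk(self, rl, re):
        return Timescales(0, 0, 1, rl, re, rl, re)

    def test_limits(self):
        assert p_end_joining_given_constrained(self.mk(0.0, 0.0)) == 1.0
        assert p_end_joining_given_constrained(self.mk(np.inf, 0.0)) == 0.0
        assert p_end_joining_given_constrained(self.mk(1e9, 0.0)) < 1e-9

    def test_strictly_decreasing_in_each_ratio(self):
        grid = np.linspace(0, 4, 9)
        for re in (0.1, 1.0):
            vals = [p_end_joining_given_constrained(self.mk(rl, re)) for rl in grid]
            assert all(a > b for a, b in zip(vals, vals[1:]))
        for rl in (0.1, 1.0):
            vals = [p_end_joining_given_constrained(self.mk(rl, re)) for re in grid]
            assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_loading_ratio_dominates_at_moderate_ratios(self):
        # in the regime rho_l < ~1 the derivative in the loading ratio is
        # steeper than in the extrusion ratio
        eps = 1e-6
        for rl, re in ((0.2, 0.5), (0.3, 0.3), (0.6, 0.6)):
            p0 = p_end_joining_given_constrained(self.mk(rl, re))
            dl = (p0 - p_end_joining_given_constrained(self.mk(rl + eps, re))) / eps
            de = (p0 - p_end_joining_given_constrained(self.mk(rl, re + eps))) / eps
            assert dl > de > 0


class TestPSynapsis:
    def test_zero_coverage_gives_zero(self):
        assert p_synapsis(TheoryParams(lam=1e-3, d=1000.0)) < 1e-5

    @pytest.mark.parametrize("axis,values", [
        ("w", [1, 2, 4, 8, 16]),
        ("F", [1, 250, 500, 750, 1000, 5000, 10000]),
        ("alpha0", [0.0, 0.05, 0.10, 0.20]),
    ])
    def test_monotone_along_mechanism_axes(self, axis, values):
        base = dict(lam=250.0, d=125.0, b=0.5)
        ps = [p_synapsis(TheoryParams(**base, **{axis: v})) for v in values]
        assert all(a <= b + 1e-12 for a, b in zip(ps, ps[1:]))

    def test_monotone_in_processivity_ratio(self):
        ps = [p_synapsis(TheoryParams(lam=125.0 * r, d=125.0, b=0.5))
              for r in (0.5, 1.0, 2.0)]
        assert ps[0] <= ps[1] <= ps[2]


class TestLoadingFraction:
    @pytest.mark.parametrize("F,S,expected", [
        (1, 10_000, 2 / 9_998 / (1 + 2 / 9_998)),  # ~0.02%
        (1000, 10_000, 2000 / 11_998),
        (10_000, 10_000, 20_000 / 29_998),
    ])
    def test_closed_form(self, F, S, expected):
        assert expected_dsb_loading_fraction(F, S) == pytest.approx(expected, rel=1e-12)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            expected_dsb_loading_fraction(0.5, 10_000)
        with pytest.raises(ValueError):
            expected_dsb_loading_fraction(10, 2)


def test_mean_loop_length_between_collision_cap_and_processivity():
    p = TheoryParams(lam=300, d=240, b=0.0)
    assert 0 < mean_loop_length(p) < 300
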