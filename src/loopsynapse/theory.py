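"""Analytical theory of LEF-mediated DSB end synapsis.

The probability of synapsis factorizes as

    P_synapsis = P_constrained * P_end-joining|constrained

**Coverage.**  ``P_constrained`` is the steady-state fraction of the genome
inside at least one extruded loop.  Each LEF's lifecycle is modelled as a
continuous-time Markov chain over the joint state of its two motors, each
motor being *moving*, *BE-latched* (stalled at a convergent boundary
element) or *collision-paused* (blocked by another LEF's motor):

* a moving motor latches at a BE at rate ``1/mu_be`` per step, where
  ``mu_be = E[residual TAD span] + (1/b - 1) E[TAD span]`` is the mean
  distance to a successful stall draw (each boundary passes with
  probability ``1-b``);
* a moving motor collides at rate ``1/(1.5 d)`` per step — the mean free
  path is of order the mean inter-LEF gap ``d``; the prefactor 1.5 is a
  mesoscopic constant calibrated once against brute-force lattice coverage
  of the collision-only (``b = 0``) model and then frozen (max error ~1
  coverage point over ``lambda/d`` in [0.3, 5]);
* a paused motor resumes when its blocking partner dies, at half the
  population mean unbinding rate (blocking partners are biased toward
  long-lived, stalled LEFs);
* the LEF unbinds at rate ``2/lambda`` per step, reduced ``w``-fold while
  a motor sits on a BE site and ``longlived_fold``-fold for the long-lived
  class; loop growth is 1 kb/step per moving motor.

Standard fundamental-matrix identities give the expected lifetime, the
time-averaged observed loop length ``l_bar`` and, per state, its share of
loop coverage and the expected remaining residence.  Treating loops as a
Poisson boolean model of intensity ``1/d`` per class then yields

    P_constrained = 1 - exp(-sum_c frac_c l_bar_c / d).

**Gap bridging.**  ``P_end-joining|constrained`` follows from a race:
the constraining LEF dies at rate ``1/tau_constrained`` (memoryless), each
side of the DSB waits for one gap-bridging loading event (rate
``1/tau_loading``) followed by a deterministic extrusion delay
``tau_extrusion``.  Integrating the race gives

    P = exp(-rho_e) * 2 / ((1 + rho_l)(2 + rho_l)),

with ``rho_l = tau_loading/tau_constrained``,
``rho_e = tau_extrusion/tau_constrained``.  The ratios are reported both
*plain* (``tau_constrained`` is the unstabilized residence ``lambda/2``
steps) and *weighted* (``tau_constrained`` averaged over the class-and-
stall-state mixture of the constraining LEF, each component weighted by
its share of loop coverage).  The weighted ratios reduce to the plain
ones when every fold is 1 and there are no long-lived LEFs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np

__all__ = [
    "TheoryParams",
    "Timescales",
    "mean_loop_length",
    "loop_coverage",
    "compute_timescales",
    "p_end_joining_given_constrained",
    "p_synapsis",
    "expected_dsb_loading_fraction",
]

_COLLISION_PATH_FACTOR = 1.5   # collision mean free path, in units of d
_RESUME_FACTOR = 0.5           # resume rate, in units of the mean unbind rate

# motor modes: M moving, B BE-latched, C collision-paused
_STATES = [tuple(sorted(s)) for s in combinations_with_replacement("MBC", 2)]
_IDX = {s: i for i, s in enumerate(_STATES)}


@dataclass
class TheoryParams:
    """Model parameters of the analytical layer (lengths in kb)."""

    lam: float = 300.0            # LEF processivity
    d: float = 240.0              # LEF separation
    b: float = 0.5                # boundary strength
    w: float = 1.0                # BE stabilization fold
    r: float = 1.0                # DSB-end stabilization fold (gap-bridging only)
    alpha0: float = 0.0           # long-lived LEF fraction
    longlived_fold: float = 20.0
    F: float = 1.0                # targeted loading fold at DSB-end sites
    v: float = 0.5                # one-sided extrusion speed, kb/s
    dsb_spacing_kb: float = 10_000.0
    be_spacing_range_kb: tuple[float, float] = (200.0, 1200.0)

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.d <= 0:
            raise ValueError("processivity and separation must be positive")
        if not 0.0 <= self.b <= 1.0:
            raise ValueError("boundary strength must lie in [0, 1]")
        if not 0.0 <= self.alpha0 <= 1.0:
            raise ValueError("long-lived fraction must lie in [0, 1]")
        if min(self.w, self.r, self.F, self.longlived_fold) < 1.0:
            raise ValueError("stabilization/loading folds must be >= 1")

    @classmethod
    def from_sim_config(cls, config) -> "TheoryParams":
        return cls(
            lam=config.lef_processivity_kb,
            d=config.lef_separation_kb,
            b=config.boundary_strength,
            w=config.be_stabilization_fold,
            r=config.dsb_stabilization_fold,
            alpha0=config.longlived_fraction,
            longlived_fold=config.longlived_fold,
            F=config.targeted_loading_fold,
            v=config.extrusion_speed_kb_per_s / 2.0,
            dsb_spacing_kb=config.dsb_spacing_kb,
            be_spacing_range_kb=tuple(config.be_spacing_range_kb),
        )

    @property
    def step_seconds(self) -> float:
        """Seconds per Monte Carlo step (1 kb per motor per step)."""
        return 1.0 / self.v

    @property
    def mean_tad_kb(self) -> float:
        lo, hi = self.be_spacing_range_kb
        return (lo + hi) / 2.0

    @property
    def mean_stall_distance_kb(self) -> float:
        """Mean distance a motor extrudes before latching at a BE."""
        lo, hi = self.be_spacing_range_kb
        es = (lo + hi) / 2.0
        es2 = (lo * lo + lo * hi + hi * hi) / 3.0
        resid = es2 / (2.0 * es)
        if self.b <= 0.0:
            return math.inf
        return resid + (1.0 / self.b - 1.0) * es


@dataclass
class Timescales:
    """The three synapsis timescales (seconds) and their ratios."""

    tau_loading: float
    tau_extrusion: float
    tau_constrained: float
    ratio_loading: float
    ratio_extrusion: float
    weighted_ratio_loading: float
    weighted_ratio_extrusion: float


class _ClassStats:
    """Fundamental-matrix expectations for one LEF class (units: steps).

    ``u``: unbind rate off BEs (``u/w`` while a motor occupies one);
    ``s_b``/``s_c``: per-moving-motor BE-latch / collision rates;
    ``rho``: resume rate of a collision-paused motor.
    """

    def __init__(self, u: float, w: float, s_b: float, s_c: float, rho: float):
        if u <= 0.0:
            self.ET = math.inf
            self.lbar = math.inf
            self.A = np.full(len(_STATES), math.inf)
            self.R = np.full(len(_STATES), math.inf)
            return
        n = len(_STATES)
        Q = np.zeros((n, n))
        kill = np.zeros(n)
        growth = np.zeros(n)
        for i, (a, bm) in enumerate(_STATES):
            kill[i] = u / w if "B" in (a, bm) else u
            growth[i] = float(a == "M") + float(bm == "M")
            for which, other in ((a, bm), (bm, a)):
                if which == "M":
                    Q[i, _IDX[tuple(sorted(("B", other)))]] += s_b
                    Q[i, _IDX[tuple(sorted(("C", other)))]] += s_c
                elif which == "C" and rho > 0.0:
                    Q[i, _IDX[tuple(sorted(("M", other)))]] += rho
        np.fill_diagonal(Q, 0.0)
        for i in range(n):
            Q[i, i] = -(Q[i].sum() + kill[i])
        M = np.linalg.inv(-Q)            # M[i, j]: expected time in j starting from i
        start = _IDX[("M", "M")]
        O = M[start]                      # occupation times from loading
        self.R = M.sum(axis=1)            # expected remaining lifetime per state
        self.ET = float(O.sum())
        # A[j] = E[integral of L(t) over time spent in state j] per lifecycle
        self.A = (growth * O) @ M
        self.lbar = float(self.A.sum() / self.ET)


def _classes(params: TheoryParams) -> list[tuple[float, _ClassStats]]:
    u = 2.0 / params.lam
    mu_be = params.mean_stall_distance_kb
    s_b = 0.0 if math.isinf(mu_be) else 1.0 / mu_be
    s_c = 1.0 / (_COLLISION_PATH_FACTOR * params.d)
    a0 = params.alpha0
    rho = _RESUME_FACTOR * ((1.0 - a0) * u + a0 * u / params.longlived_fold)
    out = []
    if a0 < 1.0:
        out.append((1.0 - a0, _ClassStats(u, params.w, s_b, s_c, rho)))
    if a0 > 0.0:
        out.append((a0, _ClassStats(u / params.longlived_fold, params.w, s_b, s_c, rho)))
    return out


def mean_loop_length(params: TheoryParams) -> float:
    """Population mean of the time-averaged observed loop length (kb)."""
    cls = _classes(params)
    if any(math.isinf(c.ET) for _, c in cls):
        return math.inf
    return sum(f * c.lbar for f, c in cls)


def loop_coverage(params: TheoryParams) -> float:
    """P_constrained: steady-state fraction of the genome inside loops."""
    expo = 0.0
    for f, c in _classes(params):
        if math.isinf(c.lbar):
            return 1.0
        expo += f * c.lbar / params.d
    return 1.0 - math.exp(-expo)


def _coverage_weighted_residence(params: TheoryParams) -> float:
    """Expected remaining residence (steps) of the LEF covering a random
    covered site, i.e. of a typical constraining LEF at break time."""
    cls = _classes(params)
    num = 0.0
    den = 0.0
    for f, c in cls:
        if math.isinf(c.ET):
            return math.inf
        share = f * c.A / c.ET
        num += float((share * c.R).sum())
        den += float(share.sum())
    if den <= 0.0:
        return params.lam / 2.0
    return num / den


def compute_timescales(params: TheoryParams, gap_kb: float | None = None,
                       constraining_at_be: bool = False) -> Timescales:
    """Loading / extrusion / constraining timescales for a given gap.

    ``gap_kb`` is the one-sided unextruded gap between a DSB end and the
    innermost constraining motor; by default half the mean observed loop
    length (a DSB lands uniformly inside its covering loop).  With
    ``constraining_at_be`` the constraining LEF is taken to be latched at
    BEs on both sides (remaining residence ``w * lambda / 2`` steps)
    instead of the coverage-weighted mixture.
    """
    if gap_kb is None:
        lbar = mean_loop_length(params)
        gap_kb = lbar / 2.0 if math.isfinite(lbar) else params.mean_tad_kb / 2.0
    step_s = params.step_seconds
    # Loading: unbind/reload events per step genome-wide are N * mean(1/E[T]);
    # a fraction (F + g) / (G + 2 n (F - 1)) of them lands in this side's gap
    # or on its end site; G cancels against N = G/d.
    cls = _classes(params)
    kbar = sum(f / c.ET for f, c in cls)
    dilution = 1.0 + 2.0 * (params.F - 1.0) / params.dsb_spacing_kb
    if kbar <= 0.0:
        tau_loading = math.inf
    else:
        tau_loading = params.d * dilution / (kbar * (params.F + gap_kb)) * step_s
    tau_extrusion = gap_kb * step_s  # one lattice site per step into the gap
    base_R = params.lam / 2.0
    if constraining_at_be:
        tau_constrained = params.w * base_R * step_s
    else:
        tau_constrained = _coverage_weighted_residence(params) * step_s
    ratio_l = tau_loading / (base_R * step_s)
    ratio_e = tau_extrusion / (base_R * step_s)
    if math.isinf(tau_constrained):
        wr_l = wr_e = 0.0
    else:
        wr_l = tau_loading / tau_constrained
        wr_e = tau_extrusion / tau_constrained
    return Timescales(tau_loading, tau_extrusion, tau_constrained,
                      ratio_l, ratio_e, wr_l, wr_e)


def p_end_joining_given_constrained(ts: Timescales, weighted: bool = True) -> float:
    """Probability that both gaps are bridged before the constraining LEF
    unbinds, from the exponential-race closed form."""
    rho_l = ts.weighted_ratio_loading if weighted else ts.ratio_loading
    rho_e = ts.weighted_ratio_extrusion if weighted else ts.ratio_extrusion
    if math.isinf(rho_l) or math.isinf(rho_e):
        return 0.0
    return math.exp(-rho_e) * 2.0 / ((1.0 + rho_l) * (2.0 + rho_l))


def p_synapsis(params: TheoryParams, gap_kb: float | None = None) -> float:
    """P_synapsis = P_constrained * P_end-joining|constrained; never exceeds
    the coverage factor."""
    cov = loop_coverage(params)
    if cov <= 0.0:
        return 0.0
    ts = compute_timescales(params, gap_kb=gap_kb)
    return cov * p_end_joining_given_constrained(ts)


def expected_dsb_loading_fraction(F: float, dsb_spacing_kb: float) -> float:
    """Expected fraction of LEF loading events landing on DSB-end sites.

    With one DSB (two end sites of weight ``F`` each) per ``S`` lattice
    sites, the fraction is ``2F / (2F + S - 2)``.
    """
    if F < 1.0:
        raise ValueError("targeted loading fold must be >= 1")
    S = float(dsb_spacing_kb)
    if S < 3.0:
        raise ValueError("DSB spacing must be at least 3 kb")
    return 2.0 * F / (2.0 * F + S - 2.0)
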