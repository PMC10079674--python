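"""Survival-style statistics for synapsis outcomes.

Synapsis experiments yield, per DSB, either an observed synapsis time
(success), a censoring time (the constraining LEF was lost, or the run
ended), or an immediate failure.  The estimators here mirror standard
practice for such right-censored data: a distribution-free empirical CDF
with Dvoretzky-Kiefer-Wolfowitz (DKW) confidence bands, a censored
exponential maximum-likelihood mean, the Kaplan-Meier restricted mean, and
a permutation test for mean differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SynapsisCurve",
    "synapsis_cdf_dkw",
    "censored_exponential_mean",
    "permutation_test_mean",
    "km_mean",
    "outcome_durations",
]


def outcome_durations(outcomes: pd.DataFrame, time_col: str = "time_min"):
    """Split an outcome table into (durations, event_observed) arrays.

    Successes are events; failures and censored records contribute their
    exposure time as right-censored observations.
    """
    t = outcomes[time_col].to_numpy(dtype=float)
    ev = (outcomes["result"] == "success").to_numpy()
    return t, ev


@dataclass
class SynapsisCurve:
    """Empirical cumulative synapsis probability with a DKW band.

    The denominator counts *all* DSBs, so the curve plateaus below 1 when
    efficiency < 1.
    """

    times: np.ndarray
    cdf: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    n_events: int
    alpha: float

    @property
    def half_band(self) -> float:
        return float(np.sqrt(np.log(2.0 / self.alpha) / (2.0 * self.n_events)))


def synapsis_cdf_dkw(outcomes: pd.DataFrame, alpha: float = 0.05,
                     time_col: str = "time_min") -> SynapsisCurve:
    """Empirical CDF of synapsis times over all DSBs with simultaneous
    DKW confidence bands of level ``1 - alpha``."""
    if len(outcomes) == 0:
        raise ValueError("no outcomes")
    n = len(outcomes)
    succ = np.sort(outcomes.loc[outcomes["result"] == "success", time_col].to_numpy(dtype=float))
    if len(succ):
        times = succ
        cdf = np.arange(1, len(succ) + 1) / n
    else:
        times = np.array([0.0])
        cdf = np.array([0.0])
    eps = np.sqrt(np.log(2.0 / alpha) / (2.0 * n))
    return SynapsisCurve(times, cdf, np.clip(cdf - eps, 0.0, 1.0),
                         np.clip(cdf + eps, 0.0, 1.0), n, alpha)


def censored_exponential_mean(durations, event_observed, alpha: float = 0.05):
    """Exponential MLE of the mean with right-censored data.

    The MLE is (total exposure time)/(number of events); the confidence
    interval uses the chi-square pivot 2 T / theta ~ chi2(2k) at k observed
    events.
    """
    t = np.asarray(durations, dtype=float)
    ev = np.asarray(event_observed, dtype=bool)
    k = int(ev.sum())
    if k == 0:
        raise ValueError("censored exponential MLE requires at least one observed event")
    total = float(t.sum())
    mean = total / k
    lo = 2.0 * total / sps.chi2.ppf(1.0 - alpha / 2.0, 2 * k)
    hi = 2.0 * total / sps.chi2.ppf(alpha / 2.0, 2 * k)
    return mean, (lo, hi)


def permutation_test_mean(group_a, group_b, n_perm: int = 10_000,
                          alternative: str = "less", seed: int = 0,
                          exact: bool = False) -> float:
    """One-sided permutation test on the difference of means.

    ``alternative="less"`` tests mean(A) < mean(B).  Monte Carlo p-values
    use the add-one correction p = (1 + #extreme) / (1 + n_perm); with
    ``exact=True`` all label assignments are enumerated and the exact
    proportion is returned.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    sign = 1.0 if alternative == "less" else -1.0
    obs = sign * (a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    na = len(a)
    if exact:
        idx_all = range(len(pooled))
        total = 0
        extreme = 0
        for comb in combinations(idx_all, na):
            mask = np.zeros(len(pooled), dtype=bool)
            mask[list(comb)] = True
            stat = sign * (pooled[mask].mean() - pooled[~mask].mean())
            total += 1
            if stat <= obs + 1e-12:
                extreme += 1
        return extreme / total
    rng = np.random.default_rng(seed)
    extreme = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        stat = sign * (perm[:na].mean() - perm[na:].mean())
        if stat <= obs + 1e-12:
            extreme += 1
    return (1 + extreme) / (1 + n_perm)


def km_mean(durations, event_observed):
    """Kaplan-Meier restricted mean survival time up to the largest
    observed event (product-limit estimator; censored records enter the
    risk set only)."""
    from lifelines import KaplanMeierFitter
    from lifelines.utils import restricted_mean_survival_time

    t = np.asarray(durations, dtype=float)
    ev = np.asarray(event_observed, dtype=bool)
    if ev.sum() == 0:
        raise ValueError("Kaplan-Meier mean requires at least one observed event")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=ev)
    horizon = float(t[ev].max())
    return float(restricted_mean_survival_time(kmf, t=horizon))
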