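"""Permutation tests for preferred and avoided associations.

The null model permutes group memberships while holding the sampling design
fixed: every swap move exchanges two individuals between two groups, so group
sizes and each individual's total number of group memberships never change.
Swaps restricted to groups within the same sampling period test *short-term*
preference (who you are with, given the days you were seen); swaps across
periods test *long-term* preference (which days and companions, given overall
gregariousness).

Evidence for non-random association at the population level: the observed SD
(and CV) of the dyadic HWI exceeds the permuted distribution (preference);
the observed proportion of nonzero dyads falls below it (avoidance).  At the
dyad level, a dyad is *preferred* when its observed HWI sits in the upper
tail of its permuted distribution (one-sided p ≥ 0.975) and exceeds twice the
overall mean HWI; *avoided* when it sits in the lower tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import association_matrix
from .sightings import SamplingPeriods

__all__ = ["PermutationResult", "permute_associations", "dyadic_preference_test"]

_STATS = ("mean_hwi", "sd_hwi", "cv_hwi", "prop_nonzero")


def _offdiag_stats(hwi: np.ndarray) -> dict[str, float]:
    n = hwi.shape[0]
    vals = hwi[np.triu_indices(n, k=1)]
    mean = float(vals.mean()) if vals.size else 0.0
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return {
        "mean_hwi": mean,
        "sd_hwi": sd,
        "cv_hwi": sd / mean if mean > 0 else 0.0,
        "prop_nonzero": float((vals > 0).mean()) if vals.size else 0.0,
    }


@dataclass
class PermutationResult:
    scope: str
    n_permutations: int
    flips_per_step: int
    burn_in: int
    seed: int | None
    ids: list[str]
    observed: dict[str, float]
    permuted: dict[str, np.ndarray]
    p_greater: dict[str, float]
    p_less: dict[str, float]
    hwi_observed: np.ndarray
    dyad_p_high: np.ndarray
    dyad_p_low: np.ndarray
    mean_permuted_hwi: np.ndarray
    degenerate: bool = False

    def to_dyad_frame(self) -> pd.DataFrame:
        n = len(self.ids)
        iu = np.triu_indices(n, k=1)
        return pd.DataFrame(
            {
                "idA": [self.ids[i] for i in iu[0]],
                "idB": [self.ids[j] for j in iu[1]],
                "HWI": self.hwi_observed[iu],
                "p_high": self.dyad_p_high[iu],
                "p_low": self.dyad_p_low[iu],
            }
        )


def _mutable_groups(periods: SamplingPeriods) -> list[list[list[int]]]:
    return [[list(g) for g in gs] for gs in periods.groups]


def _as_periods(periods: SamplingPeriods, groups) -> SamplingPeriods:
    return SamplingPeriods(
        ids=periods.ids,
        period_keys=periods.period_keys,
        groups=[[np.array(g, dtype=int) for g in gs] for gs in groups],
    )


def _try_swap(groups, flat_index, rng, within_period: bool, max_tries: int = 50) -> bool:
    """Attempt one valid swap move; returns whether a swap was made.

    ``flat_index`` lists (period, group) pairs with ≥1 member.  A move picks
    two distinct groups (same period when ``within_period``), one member of
    each not already present in the other, and exchanges them.
    """
    for _ in range(max_tries):
        p1, g1 = flat_index[rng.integers(len(flat_index))]
        if within_period:
            candidates = [k for k, (p, _) in enumerate(flat_index) if p == p1]
            if len(candidates) < 2:
                continue
            p2, g2 = flat_index[candidates[rng.integers(len(candidates))]]
        else:
            p2, g2 = flat_index[rng.integers(len(flat_index))]
        if (p1, g1) == (p2, g2):
            continue
        ga, gb = groups[p1][g1], groups[p2][g2]
        ia, ib = rng.integers(len(ga)), rng.integers(len(gb))
        a, b = ga[ia], gb[ib]
        if a == b or a in gb or b in ga:
            continue
        ga[ia], gb[ib] = b, a
        return True
    return False


def permute_associations(
    periods: SamplingPeriods,
    n_permutations: int = 1000,
    flips_per_step: int = 100,
    scope: str = "between_periods",
    seed: int | None = None,
    burn_in: int = 1000,
) -> PermutationResult:
    """Markov-chain group-membership permutation test.

    The chain starts from the observed data, performs ``burn_in`` swap moves,
    then records one permutation every ``flips_per_step`` further swaps,
    recomputing the full HWI matrix at each recorded state.  P-values use the
    standard +1 correction (the observed arrangement is a member of its own
    null set), so they are never exactly zero.

    ``scope`` is ``"between_periods"`` (swaps anywhere; long-term test) or
    ``"within_periods"`` (swaps confined to one period; short-term test).
    """
    if scope not in ("between_periods", "within_periods"):
        raise ValueError(f"unknown scope {scope!r}")
    rng = np.random.default_rng(seed)
    obs_matrix = association_matrix(periods)
    observed = _offdiag_stats(obs_matrix.hwi)
    n = periods.n_individuals

    groups = _mutable_groups(periods)
    flat_index = [
        (p, k) for p, gs in enumerate(groups) for k, g in enumerate(gs) if len(g) >= 1
    ]
    within = scope == "within_periods"

    degenerate = False
    if flips_per_step > 0 and len(flat_index) >= 2:
        made = sum(_try_swap(groups, flat_index, rng, within) for _ in range(burn_in))
        if burn_in > 0 and made == 0:
            degenerate = True
    elif flips_per_step > 0:
        degenerate = True
    if degenerate:
        warnings.warn(
            "no valid swap moves exist; permuted data equal observed data",
            stacklevel=2,
        )

    permuted = {k: np.empty(n_permutations) for k in _STATS}
    count_high = np.zeros((n, n))
    count_low = np.zeros((n, n))
    sum_hwi = np.zeros((n, n))
    for it in range(n_permutations):
        for _ in range(flips_per_step):
            _try_swap(groups, flat_index, rng, within)
        hwi = association_matrix(_as_periods(periods, groups)).hwi
        stats = _offdiag_stats(hwi)
        for k in _STATS:
            permuted[k][it] = stats[k]
        # mid-p tie handling: a tied permuted value contributes half to each
        # tail, so a dyad whose permuted distribution is degenerate at the
        # observed value lands at p ≈ 0.5 rather than 1 in both tails
        ties = hwi == obs_matrix.hwi
        count_high += (hwi < obs_matrix.hwi) + 0.5 * ties
        count_low += (hwi > obs_matrix.hwi) + 0.5 * ties
        sum_hwi += hwi

    denom = n_permutations + 1
    p_greater = {
        k: (1 + int((permuted[k] >= observed[k]).sum())) / denom for k in _STATS
    }
    p_less = {k: (1 + int((permuted[k] <= observed[k]).sum())) / denom for k in _STATS}
    return PermutationResult(
        scope=scope,
        n_permutations=n_permutations,
        flips_per_step=flips_per_step,
        burn_in=burn_in,
        seed=seed,
        ids=list(periods.ids),
        observed=observed,
        permuted=permuted,
        p_greater=p_greater,
        p_less=p_less,
        hwi_observed=obs_matrix.hwi,
        dyad_p_high=(count_high + 1) / denom,
        dyad_p_low=(count_low + 1) / denom,
        mean_permuted_hwi=sum_hwi / max(n_permutations, 1),
        degenerate=degenerate,
    )


def dyadic_preference_test(
    result: PermutationResult,
    factor: float = 2.0,
    p_threshold: float = 0.975,
) -> pd.DataFrame:
    """Classify dyads as preferred / avoided from a permutation result.

    Preferred: one-sided upper-tail p ≥ ``p_threshold`` *and* observed HWI
    greater than ``factor`` × the overall mean HWI (the magnitude screen
    keeps statistically extreme but biologically trivial dyads out).
    Avoided: one-sided lower-tail p ≥ ``p_threshold`` (equivalently, upper
    p ≤ 1 − threshold).
    """
    frame = result.to_dyad_frame()
    mean_hwi = result.observed["mean_hwi"]
    frame["preferred"] = (frame["p_high"] >= p_threshold) & (
        frame["HWI"] > factor * mean_hwi
    )
    frame["avoided"] = frame["p_low"] >= p_threshold
    return frame
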