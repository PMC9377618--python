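"""Standardized lagged association rates (SLAR) and exponential model fits.

The SLAR g(τ) estimates the probability that, given B was an associate of A
in some sampling period, a randomly chosen *identified* associate of A one
lag τ later is that same companion.  Standardizing by the number of
identified associates makes the rate robust to incomplete identification of
groups.  For each ordered pair of periods (t, u) with lag in a bin, and each
individual A with identified associates in both periods, the event
contributes

    numerator   |S_A(t) ∩ S_A(u)| / |S_A(u)|
    denominator 1

summed over both time directions, where S_A(p) is A's associate set in
period p.  A population of permanent, always-detected companions has
g(τ) = 1 at every lag; random re-assortment drives g(τ) down to the null
rate, the expectation when group membership is random over the whole
population, in which case a randomly chosen later associate of A falls in
A's earlier associate set with probability deg_A(t) / (n − 1).

Four exponential decay models describe how companionship persists:

    CC     g(τ) = a                       constant companions
    CA     g(τ) = a·exp(−bτ)              casual acquaintances
    CC+CA  g(τ) = a + c·exp(−bτ)          both components
    CA+CA  g(τ) = a·exp(−bτ) + c·exp(−dτ) two acquaintance time scales

They are fit by maximizing a binomial quasi-likelihood on the per-bin event
counts and ranked by QAIC; precision comes from a delete-one-block jackknife
over contiguous spans of sampling periods.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .sightings import SamplingPeriods

__all__ = [
    "SlarCurve",
    "SlarModelFit",
    "slar_estimate",
    "fit_slar_models",
    "jackknife_se",
    "default_lag_bins",
    "MODEL_FORMS",
]


def _period_times(periods: SamplingPeriods) -> np.ndarray:
    """Period keys as day offsets from the first period."""
    keys = periods.period_keys
    try:
        t = pd.to_datetime(keys)
        return (t - t[0]).days.to_numpy().astype(float)
    except (TypeError, ValueError):
        return np.asarray(keys, dtype=float)


def default_lag_bins(max_lag: float, n_bins: int = 10) -> np.ndarray:
    """Log-spaced lag bin edges covering (0, max_lag]."""
    if max_lag < 1:
        raise ValueError("max lag must be at least 1 sampling period")
    edges = np.unique(np.ceil(np.logspace(0.0, math.log10(max_lag), n_bins)))
    return np.concatenate(([0.0], edges))


@dataclass
class SlarCurve:
    bin_edges: np.ndarray
    lag: np.ndarray        # event-weighted mean lag per bin
    g: np.ndarray
    null: np.ndarray
    n_events: np.ndarray
    se: np.ndarray | None = None
    numerator: np.ndarray = field(default=None, repr=False)
    denominator: np.ndarray = field(default=None, repr=False)

    def nonempty(self) -> np.ndarray:
        return self.denominator > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag": self.lag,
                "g": self.g,
                "null": self.null,
                "n_events": self.n_events,
                "se": self.se if self.se is not None else np.nan,
            }
        )


def _association_arrays(periods: SamplingPeriods):
    """Per-period associate matrices, degrees, and identified counts."""
    mats, degs, n_ident = [], [], []
    for p in range(periods.n_periods):
        tog = periods.together_matrix(p)
        mats.append(tog)
        degs.append(tog.sum(axis=1))
        n_ident.append(int(periods.seen_matrix()[p].sum()))
    return mats, degs, n_ident


def _accumulate(periods: SamplingPeriods, bin_edges: np.ndarray, keep=None):
    """Per-bin numerator/denominator/null/lag-weight sums.

    ``keep`` optionally masks sampling periods (used by the jackknife).
    """
    times = _period_times(periods)
    mats = [periods.together_matrix(p) for p in range(periods.n_periods)]
    degs = [m.sum(axis=1) for m in mats]
    n_pop = periods.n_individuals
    idx = np.arange(periods.n_periods) if keep is None else np.flatnonzero(keep)

    nb = len(bin_edges) - 1
    num = np.zeros(nb)
    den = np.zeros(nb)
    null_num = np.zeros(nb)
    lag_sum = np.zeros(nb)

    for a_pos, t in enumerate(idx):
        for u in idx[a_pos + 1 :]:
            lag = abs(times[u] - times[t])
            b = np.searchsorted(bin_edges, lag, side="left") - 1
            if b < 0 or b >= nb:
                continue
            inter = (mats[t] & mats[u]).sum(axis=1).astype(float)
            for src, dst in ((t, u), (u, t)):
                mask = (degs[src] > 0) & (degs[dst] > 0)
                if not mask.any():
                    continue
                k = mask.sum()
                num[b] += float((inter[mask] / degs[dst][mask]).sum())
                # under random mixing a randomly chosen later associate of A
                # is uniform over the other n_pop - 1 individuals, so the
                # chance it belongs to A's earlier associate set is
                # deg_earlier / (n_pop - 1)
                if n_pop > 1:
                    null_num[b] += float(
                        np.minimum(degs[src][mask] / (n_pop - 1), 1.0).sum()
                    )
                else:
                    null_num[b] += float(k)
                den[b] += k
                lag_sum[b] += k * lag
    return num, den, null_num, lag_sum


def slar_estimate(
    periods: SamplingPeriods, bin_edges: np.ndarray | None = None
) -> SlarCurve:
    """Standardized lagged association rate over lag bins.

    ``bin_edges`` defaults to log-spaced bins up to the longest observed lag.
    Bins with no qualifying events are flagged by ``n_events == 0`` and carry
    ``g = nan``.
    """
    if periods.n_periods < 2:
        raise ValueError("SLAR needs at least two sampling periods")
    times = _period_times(periods)
    if bin_edges is None:
        bin_edges = default_lag_bins(float(times.max() - times.min()))
    bin_edges = np.asarray(bin_edges, dtype=float)
    num, den, null_num, lag_sum = _accumulate(periods, bin_edges)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)
        null = np.where(den > 0, null_num / np.where(den > 0, den, 1), np.nan)
        lag = np.where(den > 0, lag_sum / np.where(den > 0, den, 1), np.nan)
    return SlarCurve(
        bin_edges=bin_edges,
        lag=lag,
        g=g,
        null=null,
        n_events=den.astype(int),
        numerator=num,
        denominator=den,
    )


# ---------------------------------------------------------------------------
# Model fitting

MODEL_FORMS = {
    "CC": (lambda tau, a: np.full_like(tau, a, dtype=float), ["a"]),
    "CA": (lambda tau, a, b: a * np.exp(-b * tau), ["a", "b"]),
    "CC+CA": (lambda tau, a, c, b: a + c * np.exp(-b * tau), ["a", "c", "b"]),
    "CA+CA": (
        lambda tau, a, b, c, d: a * np.exp(-b * tau) + c * np.exp(-d * tau),
        ["a", "b", "c", "d"],
    ),
}

_BOUNDS = {"a": (1e-9, 1.0), "c": (1e-9, 1.0), "b": (1e-9, 5.0), "d": (1e-9, 5.0)}


@dataclass
class SlarModelFit:
    model: str
    params: dict[str, float]
    log_quasi_likelihood: float
    qaic: float
    delta_qaic: float | None
    converged: bool
    c_hat: float

    def predict(self, tau: np.ndarray) -> np.ndarray:
        fn, names = MODEL_FORMS[self.model]
        return np.clip(fn(np.asarray(tau, float), *[self.params[p] for p in names]), 0, 1)


def _binomial_ll(num, den, mu) -> float:
    mu = np.clip(mu, 1e-10, 1 - 1e-10)
    return float((num * np.log(mu) + (den - num) * np.log1p(-mu)).sum())


def _fit_one(model: str, lag, num, den, rng) -> tuple[dict, float, bool]:
    fn, names = MODEL_FORMS[model]
    bounds = [_BOUNDS[p] for p in names]
    g_obs = num / den
    starts = []
    base = {"a": max(g_obs.mean(), 1e-3), "c": max(g_obs.max() - g_obs.min(), 1e-3),
            "b": 1.0 / max(lag.mean(), 1.0), "d": 1.0 / max(lag.max(), 1.0)}
    starts.append([base[p] for p in names])
    for _ in range(7):
        starts.append(
            [min(max(base[p] * rng.lognormal(0, 1), lo), hi) for p, (lo, hi) in zip(names, bounds)]
        )

    def nll(theta):
        return -_binomial_ll(num, den, fn(lag, *theta))

    best = None
    for x0 in starts:
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    ok = best is not None and np.isfinite(best.fun)
    params = dict(zip(names, best.x))
    return params, -best.fun, ok


def fit_slar_models(
    curve: SlarCurve,
    models: tuple[str, ...] = ("CC", "CA", "CC+CA", "CA+CA"),
    seed: int | None = 0,
) -> list[SlarModelFit]:
    """Fit the exponential decay models and rank them by QAIC.

    The quasi-likelihood treats each bin's (numerator, denominator) event
    sums as binomial counts; the overdispersion scale ĉ is the Pearson
    X²/df of the most general converged model (floored at 1), and
    QAIC = −2 log L / ĉ + 2k.  Non-converged fits are excluded from the
    ranking with a warning.
    """
    mask = curve.nonempty()
    if mask.sum() < 3:
        raise ValueError("model fitting needs at least 3 non-empty lag bins")
    lag = curve.lag[mask]
    num = curve.numerator[mask]
    den = curve.denominator[mask]
    rng = np.random.default_rng(seed)

    raw = {}
    for model in models:
        try:
            params, ll, ok = _fit_one(model, lag, num, den, rng)
        except Exception:  # pragma: no cover - optimizer pathology
            params, ll, ok = {}, -np.inf, False
        raw[model] = (params, ll, ok)
        if not ok:
            warnings.warn(f"SLAR model {model} did not converge; excluded from ranking")

    # overdispersion from the most general (most parameters) converged model
    c_hat = 1.0
    for model in sorted(raw, key=lambda m: -len(MODEL_FORMS[m][1])):
        params, ll, ok = raw[model]
        if not ok:
            continue
        fn, names = MODEL_FORMS[model]
        mu = np.clip(fn(lag, *[params[p] for p in names]), 1e-10, 1 - 1e-10)
        df = len(lag) - len(names)
        if df > 0:
            x2 = float(((num - den * mu) ** 2 / (den * mu * (1 - mu))).sum())
            c_hat = max(1.0, x2 / df)
        break

    fits = []
    for model in models:
        params, ll, ok = raw[model]
        k = len(MODEL_FORMS[model][1])
        qaic = -2.0 * ll / c_hat + 2 * k if ok else np.inf
        fits.append(
            SlarModelFit(
                model=model,
                params=params,
                log_quasi_likelihood=ll,
                qaic=qaic,
                delta_qaic=None,
                converged=ok,
                c_hat=c_hat,
            )
        )
    finite = [f.qaic for f in fits if f.converged]
    if not finite:
        raise RuntimeError("no SLAR model converged")
    best = min(finite)
    for f in fits:
        f.delta_qaic = f.qaic - best if f.converged else np.inf
    return sorted(fits, key=lambda f: f.qaic)


# ---------------------------------------------------------------------------
# Jackknife precision


def _jackknife_groups(times: np.ndarray, block_days: float) -> np.ndarray:
    """Assign each sampling period to a contiguous block of ``block_days``."""
    return ((times - times.min()) // block_days).astype(int)


def jackknife_se(
    periods: SamplingPeriods,
    bin_edges: np.ndarray | None = None,
    block_days: float = 30.0,
    fit_models: bool = False,
    seed: int | None = 0,
) -> dict:
    """Delete-one-block jackknife SE for g(τ) (and model parameters).

    Sampling periods are grouped into contiguous blocks of ``block_days``
    days; each block is deleted in turn and the curve (and, optionally, the
    QAIC-best model's parameters) re-estimated.  The SE of an estimate θ is
    sqrt((G−1)/G · Σ_i (θ₋ᵢ − θ̄)²) over the G leave-one-out replicates.
    """
    times = _period_times(periods)
    if bin_edges is None:
        bin_edges = default_lag_bins(float(times.max() - times.min()))
    bin_edges = np.asarray(bin_edges, dtype=float)
    blocks = _jackknife_groups(times, block_days)
    labels = np.unique(blocks)
    if len(labels) < 2:
        raise ValueError("jackknife needs at least two period blocks")

    full = slar_estimate(periods, bin_edges)
    g_reps = []
    param_reps = []
    best_model = None
    if fit_models:
        best_model = fit_slar_models(full, seed=seed)[0].model
    for lab in labels:
        keep = blocks != lab
        num, den, _, _ = _accumulate(periods, bin_edges, keep=keep)
        with np.errstate(invalid="ignore", divide="ignore"):
            g_reps.append(np.where(den > 0, num / np.where(den > 0, den, 1), np.nan))
        if fit_models:
            sub = SlarCurve(
                bin_edges=bin_edges,
                lag=full.lag,
                g=g_reps[-1],
                null=full.null,
                n_events=den.astype(int),
                numerator=num,
                denominator=den,
            )
            fits = fit_slar_models(sub, models=(best_model,), seed=seed)
            param_reps.append(fits[0].params)

    g_reps = np.array(g_reps)
    gg = len(labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(g_reps, axis=0)
        se = np.sqrt((gg - 1) / gg * np.nansum((g_reps - mean) ** 2, axis=0))
    out = {"se_g": se, "n_blocks": gg, "curve": full}
    full.se = se
    if fit_models:
        names = list(param_reps[0])
        arr = np.array([[p[n] for n in names] for p in param_reps])
        pm = arr.mean(axis=0)
        pse = np.sqrt((gg - 1) / gg * ((arr - pm) ** 2).sum(axis=0))
        out["model"] = best_model
        out["se_params"] = dict(zip(names, pse))
    return out
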