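"""Standardized lagged association rates and exponential model selection.

Estimates g(τ) — the probability that a companion is retained after a lag
of τ days — with jackknife standard errors over 30-day blocks, then fits
the four exponential duration models (constant companions, casual
acquaintances, and their mixtures) and ranks them by QAIC.
"""

from socpod import (
    SimulationConfig,
    build_sampling_periods,
    fit_slar_models,
    jackknife_se,
    simulate_population,
)

catalog, _ = simulate_population(SimulationConfig(seed=5, n_days=180))
periods = build_sampling_periods(catalog)

jk = jackknife_se(periods, block_days=30.0)
curve = jk["curve"]
print("lag (days)    g(tau)   null    SE      events")
for row in curve.to_frame().itertuples():
    if row.n_events:
        print(f"{row.lag:9.1f}  {row.g:7.3f}  {row.null:.3f}  {row.se:.4f}  {row.n_events:7d}")

fits = fit_slar_models(curve, seed=5)
print("\nmodel ranking by QAIC (overdispersion c-hat "
      f"= {fits[0].c_hat:.2f}):")
for f in fits:
    params = ", ".join(f"{k}={v:.3g}" for k, v in f.params.items())
    print(f"  {f.model:6s} dQAIC = {f.delta_qaic:8.1f}   {params}")
print(f"\nbest model: {fits[0].model} — association persists above the null"
      " rate, i.e. companionships are not transient.")
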