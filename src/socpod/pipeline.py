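"""End-to-end orchestration: catalog → network → clusters → SLAR → abundance.

`run_pipeline` executes the enabled stages in order on either a simulated
catalog or a sightings CSV, writes each stage's tabular outputs plus a
machine-readable ``summary.json`` into the output directory, and returns the
summary as a dict.  With a fixed configuration and seed the summary is
byte-identical between runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import cmr, community, permutation, simulate, slar
from .sightings import (
    build_capture_histories,
    build_sampling_periods,
    filter_usable,
    read_sightings,
    write_sightings,
)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("socpod.pipeline")

STAGES = ("simulate", "associations", "permtest", "clusters", "slar", "abundance")


@dataclass
class PipelineConfig:
    """One configuration drives every stage.

    Either ``simulation`` (keyword arguments for
    :class:`socpod.simulate.SimulationConfig`) or ``input_csv`` must be
    given.  ``min_sightings`` is the inclusion threshold for the network
    stages (default 7 resighting days); ``theta`` is the marked proportion
    used to scale marked abundance to total abundance (1.0 = all animals
    identifiable).
    """

    input_csv: str | None = None
    simulation: dict | None = None
    output_dir: str = "socpod_output"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    min_sightings: int = 7
    ltm_only: bool = False
    n_permutations: int = 1000
    flips_per_step: int = 100
    permutation_scopes: tuple[str, ...] = ("between_periods", "within_periods")
    linkage_method: str = "average"
    mantel_permutations: int = 999
    slar_block_days: float = 30.0
    cmr_models: tuple[str, ...] = ("M0", "Mt")
    cmr_spec: dict = field(default_factory=dict)
    sessions: dict | None = None
    theta: float = 1.0

    def __post_init__(self):
        if self.min_sightings < 1:
            raise ValueError("min_sightings must be ≥ 1")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if "simulate" not in self.stages and self.simulation is None:
            if self.input_csv is None:
                raise ValueError("either a simulation config or an input CSV is required")
            if not Path(self.input_csv).exists():
                raise FileNotFoundError(self.input_csv)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("stages", "cmr_models", "permutation_scopes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs before it are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages and return (and write) the summary bundle."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(8)
    child = {name: s for name, s in zip(
        ("simulate", "permtest_between", "permtest_within", "mantel", "slar", "cmr", "theta", "spare"),
        seeds,
    )}
    to_int = lambda ss: int(ss.generate_state(1)[0] % (2**31))  # noqa: E731
    summary: dict = {"seed": config.seed, "stages": list(config.stages)}

    def stage(name):
        return name in config.stages

    # --- input -------------------------------------------------------------
    try:
        if stage("simulate"):
            sim_cfg = simulate.SimulationConfig(
                **{**(config.simulation or {}), "seed": to_int(child["simulate"])}
            )
            df, truth = simulate.simulate_population(sim_cfg)
            write_sightings(df, out / "sightings.csv")
            with open(out / "truth.json", "w") as fh:
                json.dump(_jsonable(truth), fh, indent=1, sort_keys=True)
            summary["simulate"] = {
                "n_individuals": truth["N_true"],
                "n_records": len(df),
                "theta_true": truth["theta_true"],
            }
        else:
            df = read_sightings(config.input_csv)
            truth = None
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate" if stage("simulate") else "input", e) from e

    df = filter_usable(df, ltm_only=config.ltm_only)
    periods_all = build_sampling_periods(df)
    counts = dict(zip(periods_all.ids, periods_all.sightings_per_individual()))
    keep = [i for i, c in counts.items() if c >= config.min_sightings]
    network_df = df[df["individual_id"].isin(keep)]
    summary["input"] = {
        "n_records": int(len(df)),
        "n_individuals": int(len(counts)),
        "n_network_individuals": int(len(keep)),
        "min_sightings": config.min_sightings,
    }

    periods = matrix = None
    if len(keep) >= 2:
        periods = build_sampling_periods(network_df)
        matrix = assoc.association_matrix(periods)

    # --- associations ------------------------------------------------------
    if stage("associations"):
        try:
            if matrix is None:
                raise ValueError("fewer than 2 individuals pass the sightings threshold")
            summ = assoc.summarize(matrix)
            s2h, reject = assoc.preferred_power_rule(
                summ.social_differentiation, summ.mean_associates
            )
            matrix.to_square_frame().to_csv(out / "hwi_matrix.csv")
            matrix.to_long_frame().to_csv(out / "dyads.csv", index=False)
            summ.per_individual.to_csv(out / "individual_summary.csv", index=False)
            summary["associations"] = {
                "mean_hwi": summ.mean_hwi,
                "sd_hwi": summ.sd_hwi,
                "S": summ.social_differentiation,
                "H": summ.mean_associates,
                "S2H": s2h,
                "reject_no_preferred": bool(reject),
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("associations", e) from e

    # --- permutation tests -------------------------------------------------
    if stage("permtest"):
        try:
            perm_summary = {}
            for scope in config.permutation_scopes:
                key = "permtest_between" if scope == "between_periods" else "permtest_within"
                res = permutation.permute_associations(
                    periods,
                    n_permutations=config.n_permutations,
                    flips_per_step=config.flips_per_step,
                    scope=scope,
                    seed=to_int(child[key]),
                )
                dyads = permutation.dyadic_preference_test(res)
                dyads.to_csv(out / f"dyad_tests_{scope}.csv", index=False)
                perm_summary[scope] = {
                    "observed": res.observed,
                    "p_sd_greater": res.p_greater["sd_hwi"],
                    "p_cv_greater": res.p_greater["cv_hwi"],
                    "p_prop_nonzero_less": res.p_less["prop_nonzero"],
                    "n_preferred_dyads": int(dyads["preferred"].sum()),
                    "n_avoided_dyads": int(dyads["avoided"].sum()),
                }
            summary["permtest"] = perm_summary
        except Exception as e:  # noqa: BLE001
            raise StageError("permtest", e) from e

    # --- clusters ----------------------------------------------------------
    partition = None
    if stage("clusters"):
        try:
            tree = community.cluster_hwi(matrix, method=config.linkage_method)
            best = community.best_partition_by_modularity(tree)
            ccc = community.cophenetic_correlation(tree, matrix)
            partition = best.partition
            best.partition_frame().to_csv(out / "clusters.csv", index=False)
            (out / "dendrogram.nwk").write_text(best.to_newick() + "\n")
            mantel = community.mantel_within_between(
                matrix,
                partition,
                n_permutations=config.mantel_permutations,
                seed=to_int(child["mantel"]),
            )
            summary["clusters"] = {
                "method": config.linkage_method,
                "n_clusters": best.n_clusters,
                "Q": best.q,
                "CCC": ccc,
                "mantel": mantel,
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("clusters", e) from e

    # --- SLAR --------------------------------------------------------------
    if stage("slar"):
        try:
            jk = slar.jackknife_se(periods, block_days=config.slar_block_days)
            curve = jk["curve"]
            curve.to_frame().to_csv(out / "slar_curve.csv", index=False)
            fits = slar.fit_slar_models(curve, seed=to_int(child["slar"]))
            pd.DataFrame(
                [
                    {"model": f.model, "qaic": f.qaic, "delta_qaic": f.delta_qaic,
                     **{f"param_{k}": v for k, v in f.params.items()}}
                    for f in fits
                ]
            ).to_csv(out / "slar_models.csv", index=False)
            summary["slar"] = {
                "best_model": fits[0].model,
                "ranking": [(f.model, f.delta_qaic) for f in fits],
                "c_hat": fits[0].c_hat,
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("slar", e) from e

    # --- abundance ---------------------------------------------------------
    if stage("abundance"):
        try:
            sessions = config.sessions
            if sessions is None and df["session"].notna().any():
                cmr_df = df[df["session"].notna()]
            elif sessions is not None:
                cmr_df = df
            else:
                raise ValueError("abundance stage needs session assignments")
            table = build_capture_histories(cmr_df, sessions=sessions)
            table.to_frame().to_csv(out / "capture_histories.csv", index=False)
            fits = []
            for k, model in enumerate(config.cmr_models):
                spec = cmr.AugmentedModelSpec(
                    model=model,
                    seed=to_int(child["cmr"]) + k,
                    **config.cmr_spec,
                )
                fits.append(cmr.fit_closed_cmr(table, spec))
            ranked = cmr.compare_models(fits) if len(fits) > 1 else None
            if ranked is not None:
                ranked.to_csv(out / "abundance_models.csv", index=False)
            abund = {}
            for f in fits:
                tot = cmr.total_abundance(f, config.theta)
                abund[f.model] = {
                    **f.summary(),
                    "n_total_median": tot["median"],
                    "n_total_ci": [tot["ci_low"], tot["ci_high"]],
                    "theta": config.theta,
                }
            summary["abundance"] = {
                "n_observed": table.n_individuals,
                "n_t": table.n_t.tolist(),
                "fits": abund,
                "best_model": ranked.iloc[0]["model"] if ranked is not None else fits[0].model,
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("abundance", e) from e

    summary = _jsonable(summary)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    with open(out / "run_config.json", "w") as fh:
        json.dump(_jsonable(asdict(config)), fh, indent=1, sort_keys=True)
    return summary
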