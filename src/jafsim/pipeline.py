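"""End-to-end bias experiments: simulate a scenario, fit candidate models,
compare them, and measure how far model choice and divergence-time estimates
drift from the simulated truth.

The central quantities, per scenario:

* ``ts_mis`` -- estimated over simulated split time (divergence-time
  misestimation; 1 means perfect recovery);
* ``w_aic_correct`` -- summed Akaike weight of the gene-flow family
  (isolation-with-migration vs secondary contact) that actually generated
  the data;
* ``tsi_ts`` -- the inferred period of strict isolation as a fraction of
  the inferred divergence time (0 when an IM-family model wins).
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .coalsim import EpochModel, jafs_from_epochs, simulate_jafs
from .demography import ModelSpec, Scenario, ScenarioGrid
from .inference import FitResult, OptimizationSchedule, fit_model, \
    poisson_loglik
from .selection import ModelComparison
from .spectrum import Spectrum, dxy_from_jafs, fst_from_jafs, pi_from_afs

__all__ = ["BiasMetrics", "run_scenario", "run_grid", "split_time",
           "isolation_fraction", "window_stats", "RESULT_COLUMNS"]


def split_time(fit: FitResult) -> float:
    """Total divergence time of a fitted model (t_si + t_sc for secondary-
    contact models, t_s otherwise)."""
    p = fit.param_dict
    if "t_s" in p:
        return p["t_s"]
    if "t_si" in p:
        return p["t_si"] + p["t_sc"]
    raise ValueError(f"fit of {fit.model} carries no split time")


def isolation_fraction(fit: FitResult) -> float:
    """Inferred strict-isolation period as a fraction of divergence time
    (TSI/TS); zero for IM-family models."""
    p = fit.param_dict
    if "t_si" in p:
        ts = p["t_si"] + p["t_sc"]
        return p["t_si"] / ts if ts > 0 else 0.0
    return 0.0


@dataclass(frozen=True)
class BiasMetrics:
    """Bias summary of one scenario under one inference mode.

    Every model fit carries its own reference size (the profiled theta fixes
    the ancestral N of that fit), so split times are compared on the
    physical scale: ``ts_est`` is the best model's split time multiplied by
    the ratio of its profiled theta to the theta profiled under the true
    generating history, which expresses it in the simulation's own time
    units (4 N_REF generations).
    """

    scenario_id: str
    folded: bool
    ts_sim: float
    ts_est: float            # rescaled to simulation time units
    ts_mis: float            # ts_est / ts_sim
    w_aic_correct: float     # family weight of the true gene-flow scenario
    tsi_ts: float            # strict isolation fraction of the best model
    best_model: str

    def __post_init__(self):
        if self.ts_mis <= 0:
            raise ValueError("ts_mis must be positive")
        if not (0.0 <= self.w_aic_correct <= 1.0 + 1e-9):
            raise ValueError("w_aic_correct must lie in [0, 1]")
        if not (0.0 <= self.tsi_ts <= 1.0 + 1e-9):
            raise ValueError("tsi_ts must lie in [0, 1]")


def _warm_start(model: ModelSpec, fits: dict[str, FitResult]) -> np.ndarray | None:
    """Model-ladder starting point: seed a candidate from the best
    already-fitted (simpler) model, matching free parameters by name.

    A donor's total split time is divided evenly between strict isolation
    and contact when seeding an SC model, and summed when seeding an IM
    model from an SC donor.  Parameters the donor lacks keep the catalogue
    default.  The first optimization round's multi-fold perturbations
    preserve global exploration around this start.
    """
    if not fits:
        return None
    donor = max(fits.values(), key=lambda f: f.loglik)
    dp = donor.param_dict
    if "t_s" in dp:
        total = dp["t_s"]
    else:
        total = dp["t_si"] + dp["t_sc"]
    start = model.start.copy()
    for i, name in enumerate(model.param_names):
        if name in dp:
            start[i] = dp[name]
        elif name == "t_s":
            start[i] = total
        elif name in ("t_si", "t_sc"):
            start[i] = total / 2.0
    return start


def run_scenario(scenario: Scenario, candidate_models: Sequence[ModelSpec],
                 folded: bool = True,
                 schedule: OptimizationSchedule | None = None,
                 seed: int = 0, mc_reps: int = 10_000,
                 n_loci: int | None = None, warm_start: bool = True,
                 reeval_mc_reps: int | None = None,
                 ) -> tuple[BiasMetrics, ModelComparison, dict[str, FitResult]]:
    """Simulate one scenario and fit every candidate model to it.

    Candidates are fitted in order of increasing parameter count and, by
    default, each start is seeded from the best simpler fit (model ladder);
    set ``warm_start=False`` for fully independent fits.  Per-model fit
    failures are recorded and skipped; the scenario aborts only if every
    fit fails.  ``n_loci`` optionally overrides the scenario's locus count
    (for desk-scale replicates).  Fully seeded: the observed spectrum and
    every fit derive their randomness from ``seed``.

    ``reeval_mc_reps`` re-evaluates every model's best parameters on one
    shared high-resolution random stream before AIC ranking.  Each fit
    otherwise reports the likelihood of its own Monte-Carlo stream, which it
    has partly adapted to during optimization; a common validation stream
    removes that per-model tilt from the comparison, at the cost of one
    extra expectation per model.
    """
    cfg = scenario.sample_config
    if n_loci is not None:
        from dataclasses import replace
        cfg = replace(cfg, n_loci=n_loci)
    obs = simulate_jafs(scenario.demography, cfg, seed=seed, folded=folded)
    fits: dict[str, FitResult] = {}
    failures: dict[str, str] = {}
    by_name = {m.name: m for m in candidate_models}
    order = sorted(candidate_models, key=lambda m: (m.n_params, m.name))
    for model in order:
        try:
            start = _warm_start(model, fits) if warm_start else None
            fits[model.name] = fit_model(obs, model, schedule=schedule,
                                         start=start, seed=seed,
                                         mc_reps=mc_reps)
        except Exception as exc:  # recorded, not fatal
            failures[model.name] = str(exc)
    if not fits:
        raise RuntimeError(f"all fits failed for {scenario.scenario_id}: "
                           f"{failures}")
    ranked = list(fits.values())
    if reeval_mc_reps is not None:
        from .inference import expected_spectrum
        from dataclasses import replace as _replace
        eval_seed = int(np.random.SeedSequence(
            [seed & 0x7FFFFFFF, 0xCE11]).generate_state(1)[0] & 0x7FFFFFFF)
        ranked = []
        for f in fits.values():
            s = expected_spectrum(by_name[f.model], f.params, cfg.n1, cfg.n2,
                                  mc_reps=reeval_mc_reps, seed=eval_seed,
                                  folded=folded)
            ll, theta = poisson_loglik(obs, s)
            ranked.append(_replace(f, loglik=ll, theta_hat=theta))
        fits = {f.model: f for f in ranked}
    comparison = ModelComparison.from_fits(ranked)
    best = fits[comparison.best]
    # profile theta under the true generating history: the ratio of profiled
    # thetas converts the fit's time units into the simulation's
    truth = jafs_from_epochs(EpochModel.from_demography(scenario.demography),
                             cfg.n1, cfg.n2, max(mc_reps, 10_000),
                             seed=int(np.random.SeedSequence(
                                 [seed & 0x7FFFFFFF, 0x7A7]).generate_state(1)[0]
                                 & 0x7FFFFFFF))
    if folded:
        truth = truth.fold()
    _, theta_truth = poisson_loglik(obs, truth)
    ts_est = split_time(best) * best.theta_hat / theta_truth
    fam_w = comparison.family_weights()
    metrics = BiasMetrics(
        scenario_id=scenario.scenario_id,
        folded=folded,
        ts_sim=scenario.ts_sim,
        ts_est=ts_est,
        ts_mis=ts_est / scenario.ts_sim,
        w_aic_correct=fam_w.get(scenario.truth_family, 0.0),
        tsi_ts=isolation_fraction(best),
        best_model=best.model,
    )
    return metrics, comparison, fits


RESULT_COLUMNS = [
    "scenario_id", "folded", "seed", "truth_family", "ts_sim", "tsi_ts_sim",
    "best_model", "ts_est", "ts_mis", "w_aic_correct", "tsi_ts",
    "n_models_fit", "n_failures",
]


def run_grid(grid: ScenarioGrid, candidates: Sequence[ModelSpec],
             folded_modes: Sequence[bool] = (True, False),
             schedule: OptimizationSchedule | None = None,
             seeds: Sequence[int] = (1,), out_path=None,
             mc_reps: int = 10_000, n_loci: int | None = None,
             verbose: bool = False) -> pd.DataFrame:
    """Run every (scenario x folding mode x seed) combination of a grid.

    Results accumulate in a fixed-schema CSV; rows already present in
    ``out_path`` are skipped on re-run, so an interrupted grid resumes where
    it stopped and a re-run over a complete table is a no-op.
    """
    if len(grid) == 0:
        raise ValueError("empty scenario grid")
    done: set[tuple[str, bool, int]] = set()
    rows: list[dict] = []
    if out_path is not None and Path(out_path).exists():
        prev = pd.read_csv(out_path)
        rows = prev.to_dict("records")
        done = {(r["scenario_id"], bool(r["folded"]), int(r["seed"]))
                for r in rows}
    for scenario in grid:
        for folded in folded_modes:
            for seed in seeds:
                key = (scenario.scenario_id, folded, int(seed))
                if key in done:
                    continue
                metrics, comparison, fits = run_scenario(
                    scenario, candidates, folded=folded, schedule=schedule,
                    seed=seed, mc_reps=mc_reps, n_loci=n_loci)
                row = {
                    "scenario_id": metrics.scenario_id,
                    "folded": folded,
                    "seed": int(seed),
                    "truth_family": scenario.truth_family,
                    "ts_sim": scenario.ts_sim,
                    "tsi_ts_sim": scenario.tsi_ts_sim,
                    "best_model": metrics.best_model,
                    "ts_est": metrics.ts_est,
                    "ts_mis": metrics.ts_mis,
                    "w_aic_correct": metrics.w_aic_correct,
                    "tsi_ts": metrics.tsi_ts,
                    "n_models_fit": len(fits),
                    "n_failures": len(candidates) - len(fits),
                }
                rows.append(row)
                done.add(key)
                if verbose:
                    print(f"{metrics.scenario_id} folded={folded} "
                          f"seed={seed}: best={metrics.best_model} "
                          f"ts_mis={metrics.ts_mis:.2f}", file=sys.stderr)
                if out_path is not None:
                    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(
                        out_path, index=False)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def window_stats(windows: dict[str, Spectrum]) -> pd.DataFrame:
    """Summary statistics per (window-id -> jAFS) mapping: within-population
    diversities, absolute divergence, Hudson F_ST and SNP count."""
    rows = []
    for wid, jafs in windows.items():
        if jafs.ndim != 2:
            raise ValueError("window spectra must be two-dimensional")
        pi1 = pi_from_afs(Spectrum(jafs.data.sum(axis=1),
                                   mask=jafs.mask.all(axis=1)))
        pi2 = pi_from_afs(Spectrum(jafs.data.sum(axis=0),
                                   mask=jafs.mask.all(axis=0)))
        try:
            fst = fst_from_jafs(jafs)
        except ValueError:
            fst = np.nan
        rows.append({"window_id": wid, "pi1": pi1, "pi2": pi2,
                     "dxy": dxy_from_jafs(jafs), "fst": fst,
                     "S": jafs.sum()})
    return pd.DataFrame(rows)
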