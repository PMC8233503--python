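"""Fitting divergence models to an observed jAFS.

The expected spectrum of a candidate model is obtained by Monte-Carlo
branch expectation: the mean branch length subtending each (i, j) class
over ``mc_reps`` simulated genealogies, so that ``theta * cell`` is the
expected SNP count per cell.  Common random numbers are used throughout an
optimization -- every likelihood evaluation re-uses the same random stream
-- which makes the Monte-Carlo likelihood surface deterministic in the
parameters and hence optimizable.

The fit criterion is the Poisson composite likelihood standard in
AFS-based inference: cell counts are treated as independent Poisson with
mean ``theta * m_ij``; the scale ``theta`` is profiled analytically
(``theta_hat = sum(obs) / sum(model)``) and counts as one estimated
parameter in the AIC.

Optimization follows a multi-round perturbed-restart recipe: each round
draws a scheduled number of starting points by multiplying the incumbent
parameters by factors log-uniform in ``[1/fold, fold]`` and polishes each
with a bounded Nelder-Mead local search capped at a scheduled number of
iterations; the best restart seeds the next round.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, special

from .coalsim import EpochModel, jafs_from_epochs
from .demography import ModelSpec, _BOUNDS, _PARAM_KIND
from .spectrum import Spectrum

__all__ = [
    "FitResult",
    "OptimizationSchedule",
    "UnscaledParams",
    "expected_spectrum",
    "poisson_loglik",
    "fit_model",
    "fit_one_pop",
    "unscale",
    "one_pop_models",
    "OnePopModel",
    "sequence_length_from_snp_counts",
]

#: floor applied to model densities before taking logs (Monte-Carlo zeros in
#: far corners of the spectrum)
MODEL_FLOOR = 1e-12
#: default number of genealogies behind each expected spectrum
MC_REPS_DEFAULT = 20_000
_PENALTY = 1e10


# ---------------------------------------------------------------------------
# expected spectra
# ---------------------------------------------------------------------------

def expected_spectrum(model: ModelSpec, params, n1: int, n2: int,
                      mc_reps: int = MC_REPS_DEFAULT, seed: int = 0,
                      folded: bool = False) -> Spectrum:
    """Expected (density-mode) jAFS of an inference model at ``params``.

    For homogeneous models this is the branch-expectation spectrum of the
    built demography.  Heterogeneous models are disjoint mixtures

        (1 - P - Q) S(neutral) + P S(migration x factor) + Q S(sizes x hrf)

    over a barrier-island class (fraction P, both migration rates multiplied
    by the island factor) and a low-Ne class (fraction Q, every population
    size multiplied by hrf).  Deterministic given ``seed``: calls with the
    same seed share random numbers, which is what makes the Monte-Carlo
    likelihood surface smooth across parameter values.
    """
    if mc_reps < 100:
        raise ValueError("mc_reps must be at least 100")
    demo, mix = model.build(params)
    parts = [(1.0 - mix.p_island - mix.q_lowne, 1.0, 1.0)]
    if mix.p_island > 0.0:
        parts.append((mix.p_island, mix.island_m_factor, 1.0))
    if mix.q_lowne > 0.0:
        parts.append((mix.q_lowne, 1.0, mix.hrf))
    data = None
    for salt, (wgt, m_scale, s_scale) in enumerate(parts):
        ep = EpochModel.from_demography(demo, mig_scale=m_scale,
                                        size_scale=s_scale)
        s = jafs_from_epochs(ep, n1, n2, mc_reps, seed)
        data = wgt * s.data if data is None else data + wgt * s.data
    out = Spectrum(data)
    return out.fold() if folded else out


def poisson_loglik(obs: Spectrum, model: Spectrum) -> tuple[float, float]:
    """Poisson composite log-likelihood of ``obs`` under a density-mode
    ``model`` spectrum, with the scale theta profiled analytically.

    Returns ``(loglik, theta_hat)`` where ``theta_hat = sum(obs)/sum(model)``
    over unmasked cells and

        loglik = sum_cells [ d ln(theta m) - theta m - ln d! ].
    """
    if obs.shape != model.shape:
        raise ValueError("observed and model spectra have different shapes")
    if obs.folded != model.folded:
        raise ValueError("observed and model spectra have different folding")
    use = ~(obs.mask | model.mask)
    d = obs.data[use]
    if not np.any(model.data[use] > 0):
        raise ValueError("model spectrum has no mass on unmasked cells")
    m = np.maximum(model.data[use], MODEL_FLOOR)
    m_tot = m.sum()
    if not np.isfinite(m_tot):
        raise ValueError("model spectrum contains non-finite values")
    theta = float(d.sum() / m_tot)
    if theta == 0.0:
        return float(-0.0), 0.0
    lam = theta * m
    ll = float(np.sum(d * np.log(lam) - lam - special.gammaln(d + 1.0)))
    return ll, theta


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OptimizationSchedule:
    """Multi-round perturbed-restart schedule.

    ``rounds`` is a sequence of ``(n_restarts, fold, maxiter)`` triples;
    perturbation folds must be non-increasing across rounds.  The whole
    procedure can be repeated ``n_routines`` times from the original start
    to check convergence; the best routine wins.
    """

    rounds: tuple[tuple[int, float, int], ...]
    n_routines: int = 1

    def __post_init__(self):
        if len(self.rounds) < 1 or self.n_routines < 1:
            raise ValueError("need at least one round and one routine")
        folds = [f for _, f, _ in self.rounds]
        if any(f < 1.0 for f in folds):
            raise ValueError("perturbation folds must be >= 1")
        if any(a < b for a, b in zip(folds, folds[1:])):
            raise ValueError("perturbation folds must not increase")

    @classmethod
    def simulated(cls, n_routines: int = 1) -> "OptimizationSchedule":
        """Default for simulated data: three rounds of ten restarts with
        3-, 2- and 1-fold perturbations and 10/20/30 local iterations."""
        return cls(((10, 3.0, 10), (10, 2.0, 20), (10, 1.0, 30)), n_routines)

    @classmethod
    def empirical(cls, n_routines: int = 5) -> "OptimizationSchedule":
        """Heavier preset for empirical-style analyses: five rounds."""
        return cls(((30, 3.0, 30), (20, 3.0, 30), (20, 2.0, 30),
                    (20, 1.0, 30), (20, 1.0, 30)), n_routines)

    @classmethod
    def quick(cls, n_routines: int = 1) -> "OptimizationSchedule":
        """Light two-round schedule for desk-scale experiments and tests."""
        return cls(((6, 3.0, 10), (6, 1.0, 20)), n_routines)


@dataclass
class FitResult:
    """Outcome of fitting one model to one observed spectrum."""

    model: str
    family: str
    param_names: tuple[str, ...]
    params: np.ndarray
    theta_hat: float
    loglik: float
    k: int
    trace: list[tuple[int, int, int, float]] = field(default_factory=list)
    mc_reps: int = 0
    folded: bool = False

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    @property
    def param_dict(self) -> dict[str, float]:
        return dict(zip(self.param_names, map(float, self.params)))

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "family": self.family,
            "params": self.param_dict,
            "theta_hat": self.theta_hat,
            "loglik": self.loglik,
            "K": self.k,
            "AIC": self.aic,
            "mc_reps": self.mc_reps,
            "folded": self.folded,
        }


def _perturb(x: np.ndarray, fold: float, lb: np.ndarray, ub: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """Multiply each parameter by a factor log-uniform in [1/fold, fold]."""
    if fold <= 1.0:
        return x.copy()
    f = np.exp(rng.uniform(-np.log(fold), np.log(fold), size=x.size))
    return np.clip(x * f, lb, ub)


#: Monte-Carlo resolution of the early optimization rounds, as a fraction of
#: the final round's mc_reps (floored at _MC_COARSE_MIN genealogies).
_MC_COARSE_FRACTION = 0.2
_MC_COARSE_MIN = 2_000


def _multi_round_search(make_negll: Callable[[int], Callable],
                        start: np.ndarray, bounds, schedule, seed: int,
                        mc_reps: int):
    """Multi-round perturbed-restart search in log-parameter space.

    Parameters span orders of magnitude, so the local search operates on
    log-transformed coordinates.  Early rounds run on a coarser (but, via
    common random numbers, equally deterministic) Monte-Carlo likelihood
    surface; the final round and all cross-routine comparisons use the full
    ``mc_reps`` surface.  Restarts with ``fold == 1`` are identical
    deterministic searches and are collapsed into one.
    """
    lb = np.array([max(b[0], 1e-8) for b in bounds])
    ub = np.array([b[1] for b in bounds])
    zlb, zub = np.log(lb), np.log(ub)
    start = np.clip(np.asarray(start, dtype=float), lb, ub)
    n_rounds = len(schedule.rounds)
    coarse = max(_MC_COARSE_MIN, int(mc_reps * _MC_COARSE_FRACTION))
    coarse = min(coarse, mc_reps)
    best_x, best_f = None, np.inf
    trace: list[tuple[int, int, int, float]] = []
    for routine in range(schedule.n_routines):
        rng = np.random.default_rng(np.random.SeedSequence(
            [int(seed) & 0x7FFFFFFF, 0x0F17, routine]))
        x_cur = start
        round_x, round_f = start, np.inf
        for r, (n_restarts, fold, maxiter) in enumerate(schedule.rounds):
            final = r == n_rounds - 1
            negll = make_negll(mc_reps if final else coarse)
            negll_z = lambda z: negll(np.exp(np.clip(z, zlb, zub)))
            if fold <= 1.0:
                n_restarts = 1
            # Nelder-Mead needs an initial simplex wide enough to stride
            # over the Monte-Carlo ruggedness of the likelihood surface;
            # its edge (in log-parameter units) shrinks with the
            # perturbation fold across rounds.
            edge = max(0.2, 0.6 * np.log(fold))
            npar = start.size
            round_x, round_f = None, np.inf
            for j in range(n_restarts):
                x0 = _perturb(x_cur, fold, lb, ub, rng)
                if maxiter == 0:
                    fun, xo = negll(x0), x0
                else:
                    def _nm(z_init, edge_len):
                        simplex = np.clip(
                            np.vstack([z_init] +
                                      [z_init + edge_len * np.eye(npar)[i]
                                       for i in range(npar)]), zlb, zub)
                        return optimize.minimize(
                            negll_z, z_init, method="Nelder-Mead",
                            bounds=list(zip(zlb, zub)),
                            options={"maxiter": int(maxiter) * max(1, npar),
                                     "initial_simplex": simplex,
                                     "xatol": 1e-3, "fatol": 1e-3},
                        )
                    res = _nm(np.log(x0), edge)
                    if final:
                        # restart the simplex once where it collapsed: cheap
                        # insurance against premature contraction on a
                        # Monte-Carlo-rough surface
                        res2 = _nm(res.x, edge / 2.0)
                        if res2.fun < res.fun:
                            res = res2
                    fun = float(res.fun)
                    xo = np.exp(np.clip(res.x, zlb, zub))
                trace.append((routine, r, j, -fun))
                if fun < round_f:
                    round_x, round_f = np.asarray(xo, dtype=float), fun
            x_cur = round_x
        # routines are compared on the final-round (full-resolution) surface
        if round_f < best_f:
            best_x, best_f = round_x, round_f
    if best_x is None or not np.isfinite(best_f):
        raise RuntimeError("optimization produced no finite likelihood")
    return np.clip(best_x, lb, ub), best_f, trace


def fit_model(obs: Spectrum, model: ModelSpec,
              schedule: OptimizationSchedule | None = None,
              start: Sequence[float] | None = None, seed: int = 0,
              mc_reps: int = MC_REPS_DEFAULT) -> FitResult:
    """Fit a two-population model to an observed jAFS.

    The folding state of ``obs`` dictates the inference mode: model spectra
    are folded before the likelihood when the data are folded.  All
    randomness (restart perturbations and the common-random-number stream of
    the expectation engine) derives from ``seed``; two calls with identical
    arguments return identical results.
    """
    if obs.ndim != 2:
        raise ValueError("fit_model expects a two-population spectrum")
    n1, n2 = obs.sample_sizes
    eval_seed = int(np.random.SeedSequence(
        [int(seed) & 0x7FFFFFFF, 0xE7A1]).generate_state(1)[0] & 0x7FFFFFFF)

    def make_negll(reps: int) -> Callable[[np.ndarray], float]:
        def negll(x: np.ndarray) -> float:
            try:
                s = expected_spectrum(model, x, n1, n2, mc_reps=reps,
                                      seed=eval_seed, folded=obs.folded)
                ll, _ = poisson_loglik(obs, s)
            except (ValueError, FloatingPointError):
                return _PENALTY
            return -ll if np.isfinite(ll) else _PENALTY
        return negll

    x0 = model.start if start is None else np.asarray(start, dtype=float)
    best_x, _, trace = _multi_round_search(
        make_negll, x0, model.bounds,
        schedule or OptimizationSchedule.simulated(), seed, mc_reps)
    s = expected_spectrum(model, best_x, n1, n2, mc_reps=mc_reps,
                          seed=eval_seed, folded=obs.folded)
    ll, theta = poisson_loglik(obs, s)
    return FitResult(model=model.name, family=model.family,
                     param_names=model.param_names, params=best_x,
                     theta_hat=theta, loglik=ll, k=model.k_aic, trace=trace,
                     mc_reps=mc_reps, folded=obs.folded)


# ---------------------------------------------------------------------------
# one-population models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OnePopModel:
    """A single-population inference model: free parameters plus a builder
    producing the backward-time epoch model."""

    name: str
    param_names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]
    start: tuple[float, ...]
    epochs: Callable[[np.ndarray], EpochModel]

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def k_aic(self) -> int:
        return self.n_params + 1


def _snm_epochs(_: np.ndarray) -> EpochModel:
    return EpochModel.one_population([0.0], [1.0])


def _two_epoch(x: np.ndarray) -> EpochModel:
    nu, t1 = x
    return EpochModel.one_population([0.0, t1], [nu, 1.0])


def _three_epoch_bottleneck(x: np.ndarray) -> EpochModel:
    # recent epoch: exponential growth from b*nu_pres (at t2) to nu_pres now;
    # middle epoch [t2, t2+t_mid): size nu_mid; ancestral size 1 beyond.
    nu_pres, b, t2, nu_mid, t_mid = x
    t1 = t2 + t_mid
    return EpochModel.one_population(
        [0.0, t2, t1],
        [nu_pres, nu_mid, 1.0],
        [b * nu_pres, nu_mid, 1.0],
    )


def one_pop_models() -> dict[str, OnePopModel]:
    """The standard-neutral (SNM), two-epoch (2EP) and three-epoch-with-
    bottleneck-and-growth (3EPB) single-population models."""
    size_b, time_b = _BOUNDS["size"], _BOUNDS["time"]
    sev_b = _BOUNDS["sev"]
    return {
        "SNM": OnePopModel("SNM", (), (), (), _snm_epochs),
        "2EP": OnePopModel("2EP", ("nu", "t1"), (size_b, time_b),
                           (1.0, 0.1), _two_epoch),
        "3EPB": OnePopModel(
            "3EPB", ("nu_pres", "b", "t2", "nu_mid", "t_mid"),
            (size_b, sev_b, time_b, size_b, time_b),
            (1.0, 0.2, 0.05, 1.0, 0.1), _three_epoch_bottleneck),
    }


def snm_expected_afs(n: int) -> Spectrum:
    """Analytic expected AFS of the standard neutral model: cell i = 1/i."""
    data = np.zeros(n + 1)
    data[1:n] = 1.0 / np.arange(1, n)
    return Spectrum(data)


def expected_afs_one_pop(model: OnePopModel, params, n: int,
                         mc_reps: int = MC_REPS_DEFAULT, seed: int = 0,
                         folded: bool = False) -> Spectrum:
    """Expected 1-D AFS of a one-population model (analytic for SNM)."""
    if model.name == "SNM":
        s = snm_expected_afs(n)
    else:
        if mc_reps < 100:
            raise ValueError("mc_reps must be at least 100")
        ep = model.epochs(np.asarray(params, dtype=float))
        s = jafs_from_epochs(ep, n, 0, mc_reps, seed)
        s = Spectrum(s.data[:, 0])
    return s.fold() if folded else s


def fit_one_pop(obs: Spectrum, model: str | OnePopModel,
                schedule: OptimizationSchedule | None = None, seed: int = 0,
                mc_reps: int = MC_REPS_DEFAULT) -> FitResult:
    """Fit a one-population model to a 1-D AFS (same likelihood and
    schedule machinery as :func:`fit_model`; SNM needs no search)."""
    if obs.ndim != 1:
        raise ValueError("fit_one_pop expects a 1-D spectrum")
    if isinstance(model, str):
        model = one_pop_models()[model]
    n = obs.sample_sizes[0]
    eval_seed = int(np.random.SeedSequence(
        [int(seed) & 0x7FFFFFFF, 0xE7A1]).generate_state(1)[0] & 0x7FFFFFFF)

    if model.n_params == 0:
        s = expected_afs_one_pop(model, (), n, folded=obs.folded)
        ll, theta = poisson_loglik(obs, s)
        return FitResult(model=model.name, family=model.name,
                         param_names=(), params=np.array([]),
                         theta_hat=theta, loglik=ll, k=model.k_aic,
                         folded=obs.folded)

    def make_negll(reps: int) -> Callable[[np.ndarray], float]:
        def negll(x: np.ndarray) -> float:
            try:
                s = expected_afs_one_pop(model, x, n, mc_reps=reps,
                                         seed=eval_seed, folded=obs.folded)
                ll, _ = poisson_loglik(obs, s)
            except (ValueError, FloatingPointError):
                return _PENALTY
            return -ll if np.isfinite(ll) else _PENALTY
        return negll

    best_x, _, trace = _multi_round_search(
        make_negll, np.asarray(model.start, dtype=float), list(model.bounds),
        schedule or OptimizationSchedule.simulated(), seed, mc_reps)
    s = expected_afs_one_pop(model, best_x, n, mc_reps=mc_reps,
                             seed=eval_seed, folded=obs.folded)
    ll, theta = poisson_loglik(obs, s)
    return FitResult(model=model.name, family=model.name,
                     param_names=model.param_names, params=best_x,
                     theta_hat=theta, loglik=ll, k=model.k_aic, trace=trace,
                     mc_reps=mc_reps, folded=obs.folded)


# ---------------------------------------------------------------------------
# unscaling to demographic units
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnscaledParams:
    """Parameters converted to demographic units via the profiled theta."""

    n_anc: float                       # ancestral diploid size
    sizes: dict[str, float]            # diploid sizes
    times_generations: dict[str, float]
    times_years: dict[str, float]
    migration_fractions: dict[str, float]  # per-generation migrant fractions
    other: dict[str, float]


def sequence_length_from_snp_counts(s_sites: float, v_unlinked: float,
                                    v_total: float) -> float:
    """Effective total sequence length L = S x (V_U / V_T): the surveyed
    length rescaled by the fraction of variants kept after thinning to
    unlinked SNPs."""
    if min(s_sites, v_unlinked, v_total) <= 0:
        raise ValueError("all counts must be positive")
    return s_sites * (v_unlinked / v_total)


def unscale(fit: FitResult, mu: float, l_total: float,
            generation_time: float = 1.0) -> UnscaledParams:
    """Convert a fit from coalescent units to individuals, generations and
    years: N_ANC = theta_hat / (4 mu L); relative sizes scale by N_ANC,
    times by 4 N_ANC generations, scaled migration rates M by 1/(4 N_ANC).
    """
    if fit.theta_hat <= 0:
        raise ValueError("profiled theta must be positive to unscale")
    if mu <= 0 or l_total <= 0 or generation_time <= 0:
        raise ValueError("mu, l_total and generation_time must be positive")
    n_anc = fit.theta_hat / (4.0 * mu * l_total)
    sizes: dict[str, float] = {}
    gens: dict[str, float] = {}
    years: dict[str, float] = {}
    migs: dict[str, float] = {}
    other: dict[str, float] = {}
    for name, val in fit.param_dict.items():
        kind = _PARAM_KIND.get(name)
        if kind == "size":
            sizes[name] = val * n_anc
        elif kind == "time":
            gens[name] = val * 4.0 * n_anc
            years[name] = val * 4.0 * n_anc * generation_time
        elif kind == "mig":
            migs[name] = val / (4.0 * n_anc)
        else:
            other[name] = val
    return UnscaledParams(n_anc=n_anc, sizes=sizes, times_generations=gens,
                          times_years=years, migration_fractions=migs,
                          other=other)
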