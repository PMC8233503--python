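"""Two-population demographic histories, simulation scenario grids and the
inference-model catalogue.

All times are expressed in units of ``4 * N_REF`` generations and all
population sizes relative to a reference diploid size ``N_REF`` (the ms
convention).  Migration is scaled as ``M_ij = 4 * N_REF * m_ij`` where
``m_ij`` is the fraction of population *i* replaced by migrants from
population *j* each generation; backward in time a lineage in deme *i*
therefore jumps to deme *j* at rate ``M_ij`` per unit of scaled time.

The module provides

* :class:`DemographyParams` -- a full parameterisation of a two-population
  divergence history (split, secondary contact, daughter bottleneck with
  exponential regrowth, ancestral expansion or contraction);
* scenario-grid constructors mirroring a fully orthogonal simulation design
  over divergence times, bottleneck severities and ancestral size changes;
* :func:`build_model_catalogue` -- the 8 basic and 32 extended inference
  models (IM/SC x B x AE x {2N, 2M} heterogeneity mixtures).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Callable, Iterator, Sequence

import numpy as np
import yaml

__all__ = [
    "DemographyParams",
    "SampleConfig",
    "MixtureParams",
    "ModelSpec",
    "Scenario",
    "ScenarioGrid",
    "build_older_grid",
    "build_recent_grid",
    "build_model_catalogue",
    "N_REF_DEFAULT",
    "MU_DEFAULT",
    "LOCUS_LEN_DEFAULT",
]

N_REF_DEFAULT = 20_000
MU_DEFAULT = 1e-8
LOCUS_LEN_DEFAULT = 36


@dataclass
class DemographyParams:
    """Parameters of a two-population divergence history.

    Backward in time the daughter populations (sizes ``nu1``, ``nu2``
    relative to N_REF) merge into the ancestral population at ``t_s``.
    ``t_sc > 0`` selects a secondary-contact history: migration operates
    only on ``[0, t_sc)`` and the interval ``[t_sc, t_s)`` is strict
    isolation.  ``t_sc == 0`` means migration throughout divergence
    (isolation-with-migration).

    A bottleneck in population 2 is described by its severity ``b`` (size at
    the bottleneck as a fraction of ``nu2``), the time ``t_b`` at which the
    population was at its smallest (defaults to the split time) and the
    duration ``g`` of the exponential regrowth that follows it in forward
    time (i.e. the growth occupies ``[t_b - g, t_b]`` backward).
    ``nu2_ancient`` sets the size of population 2 at times deeper than
    ``t_b`` (default: the bottleneck size itself, appropriate when the
    bottleneck sits at the split or at the onset of secondary contact; grids
    that model a transient crash of an established population set it to
    ``nu2``).

    The ancestral population has size ``nu_ae`` on ``[t_s, t_s + t_ae)`` and
    ``nu_anc`` deeper than that (an expansion when ``nu_anc < nu_ae``).  An
    ancestral contraction-and-recovery is described instead by ``t_ab``: the
    ancestral size is ``nu_anc`` on ``[t_s, t_s + t_ab/2)``, drops to
    ``nu_ae`` on ``[t_s + t_ab/2, t_s + t_ab)`` and returns to ``nu_anc``
    beyond.  At most one of ``t_ae`` and ``t_ab`` may be non-zero.
    """

    nu1: float = 1.0
    nu2: float = 1.0
    t_s: float = 0.05
    t_sc: float = 0.0
    m12: float = 0.0
    m21: float = 0.0
    nu_anc: float = 1.0
    nu_ae: float = 1.0
    t_ae: float = 0.0
    t_ab: float = 0.0
    b: float = 1.0
    g: float = 0.0
    t_b: float | None = None
    nu2_ancient: float | None = None

    def __post_init__(self) -> None:
        if self.t_b is None and self.b < 1.0:
            self.t_b = self.t_s
        self.validate()

    def validate(self) -> None:
        for name in ("nu1", "nu2", "nu_anc", "nu_ae"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.t_s < 0:
            raise ValueError("t_s must be >= 0")
        if not (0.0 <= self.t_sc <= self.t_s):
            raise ValueError("need 0 <= t_sc <= t_s")
        if self.m12 < 0 or self.m21 < 0:
            raise ValueError("migration rates must be >= 0")
        if not (0.0 < self.b <= 1.0):
            raise ValueError("bottleneck severity b must be in (0, 1]")
        if self.g < 0 or self.g > self.t_s:
            raise ValueError("growth duration g must satisfy 0 <= g <= t_s")
        if self.t_ae < 0 or self.t_ab < 0:
            raise ValueError("t_ae and t_ab must be >= 0")
        if self.t_ae > 0 and self.t_ab > 0:
            raise ValueError("t_ae and t_ab are mutually exclusive")
        if self.b < 1.0:
            tb = self.t_b if self.t_b is not None else self.t_s
            if not (0.0 < tb <= self.t_s):
                raise ValueError("bottleneck time t_b must be in (0, t_s]")
            if self.g > tb:
                raise ValueError("growth duration cannot exceed t_b")
        if self.nu2_ancient is not None and self.nu2_ancient <= 0:
            raise ValueError("nu2_ancient must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DemographyParams":
        return cls(**d)


@dataclass(frozen=True)
class SampleConfig:
    """Sampling design: haploid sample sizes, number of unlinked loci, locus
    length (bp), per-base mutation rate and the reference diploid size."""

    n1: int = 20
    n2: int = 20
    n_loci: int = 1_000_000
    locus_len: int = LOCUS_LEN_DEFAULT
    mu: float = MU_DEFAULT
    n_ref: int = N_REF_DEFAULT

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 0:
            raise ValueError("need n1 >= 2 and n2 >= 0 haploid samples")
        if self.locus_len < 1 or self.n_loci < 1:
            raise ValueError("locus_len and n_loci must be >= 1")
        if self.mu < 0 or self.n_ref <= 0:
            raise ValueError("mu must be >= 0 and n_ref positive")

    @property
    def theta_locus(self) -> float:
        """Per-locus population mutation rate theta = 4 N_REF mu L."""
        theta = 4.0 * self.n_ref * self.mu * self.locus_len
        if not math.isfinite(theta) or theta < 0:
            raise ValueError("theta must be finite and non-negative")
        return theta


@dataclass(frozen=True)
class MixtureParams:
    """Genomic heterogeneity mixture.

    A fraction ``p_island`` of loci ("barrier" islands) experiences both
    migration rates multiplied by ``island_m_factor``; a disjoint fraction
    ``q_lowne`` (a coarse proxy for linked selection) experiences all
    population sizes multiplied by ``hrf``.  The two classes never overlap.
    """

    p_island: float = 0.0
    island_m_factor: float = 1.0
    q_lowne: float = 0.0
    hrf: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_island and 0.0 <= self.q_lowne):
            raise ValueError("mixture fractions must be >= 0")
        if self.p_island + self.q_lowne > 1.0 + 1e-12:
            raise ValueError("p_island + q_lowne must not exceed 1")
        if not (0.0 <= self.island_m_factor <= 1.0):
            raise ValueError("island_m_factor must be in [0, 1]")
        if not (0.0 < self.hrf <= 1.0):
            raise ValueError("hrf must be in (0, 1]")

    @property
    def is_homogeneous(self) -> bool:
        return self.p_island == 0.0 and self.q_lowne == 0.0


# ---------------------------------------------------------------------------
# Inference models
# ---------------------------------------------------------------------------

# optimisation bounds per parameter kind: generous envelopes around every
# simulated value
_BOUNDS = {
    "size": (1e-4, 100.0),
    "time": (1e-5, 10.0),
    "mig": (0.0, 50.0),
    "frac": (0.0, 0.5),
    "sev": (1e-3, 1.0),
    "factor": (0.0, 1.0),
    "hrf": (1e-3, 1.0),
}

_PARAM_KIND = {
    "nu1": "size",
    "nu2": "size",
    "nu_ae": "size",
    "t_s": "time",
    "t_si": "time",
    "t_sc": "time",
    "t_ae": "time",
    "m12": "mig",
    "m21": "mig",
    "b": "sev",
    "p_island": "frac",
    "island_m_factor": "factor",
    "q_lowne": "frac",
    "hrf": "hrf",
}

_START = {
    "nu1": 1.0,
    "nu2": 1.0,
    "t_s": 0.1,
    "t_si": 0.1,
    "t_sc": 0.05,
    "m12": 2.0,
    "m21": 2.0,
    "b": 0.2,
    "nu_ae": 2.0,
    "t_ae": 0.2,
    "p_island": 0.1,
    "island_m_factor": 0.1,
    "q_lowne": 0.1,
    "hrf": 0.1,
}


@dataclass(frozen=True)
class ModelSpec:
    """A named inference-model family.

    ``builder`` maps a free-parameter vector (ordered as ``param_names``) to
    a (:class:`DemographyParams`, :class:`MixtureParams`) pair.  ``family``
    is the gene-flow scenario the model belongs to (``"IM"`` or ``"SC"``).
    The AIC parameter count is ``n_params + 1``: the composite-likelihood
    scale theta is profiled analytically but still counts as an estimated
    parameter.
    """

    name: str
    family: str
    param_names: tuple[str, ...]
    builder: Callable[[np.ndarray], tuple[DemographyParams, MixtureParams]]

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def k_aic(self) -> int:
        return self.n_params + 1

    @property
    def bounds(self) -> list[tuple[float, float]]:
        return [_BOUNDS[_PARAM_KIND[p]] for p in self.param_names]

    @property
    def start(self) -> np.ndarray:
        return np.array([_START[p] for p in self.param_names])

    def build(self, params) -> tuple[DemographyParams, MixtureParams]:
        params = np.asarray(params, dtype=float)
        if params.shape != (self.n_params,):
            raise ValueError(
                f"{self.name} expects {self.n_params} parameters, got {params.shape}"
            )
        return self.builder(params)

    def params_from(self, demo: DemographyParams, mix: MixtureParams) -> np.ndarray:
        """Inverse of :meth:`build`: read the free parameters back."""
        out = []
        for p in self.param_names:
            if p == "t_si":
                out.append(demo.t_s - demo.t_sc)
            elif p == "t_s":
                out.append(demo.t_s)
            elif p == "t_sc":
                out.append(demo.t_sc)
            elif hasattr(demo, p):
                out.append(getattr(demo, p))
            else:
                out.append(getattr(mix, p))
        return np.array(out, dtype=float)


def _two_pop_builder(gene_flow: str, with_b: bool, with_ae: bool,
                     het_m: bool, het_n: bool):
    names: list[str] = ["nu1", "nu2"]
    if gene_flow == "SC":
        names += ["t_si", "t_sc"]
    else:
        names += ["t_s"]
    names += ["m12", "m21"]
    if with_b:
        names.append("b")
    if with_ae:
        names += ["nu_ae", "t_ae"]
    if het_m:
        names += ["p_island", "island_m_factor"]
    if het_n:
        names += ["q_lowne", "hrf"]
    names_t = tuple(names)

    def builder(x: np.ndarray):
        d = dict(zip(names_t, x))
        if gene_flow == "SC":
            t_s = d["t_si"] + d["t_sc"]
            t_sc = d["t_sc"]
        else:
            t_s = d["t_s"]
            t_sc = 0.0
        b = d.get("b", 1.0)
        # growth in B models runs from the onset of gene flow (the split for
        # IM, the secondary contact for SC) to the present
        t_b = (t_sc if gene_flow == "SC" else t_s) if with_b else None
        demo = DemographyParams(
            nu1=d["nu1"], nu2=d["nu2"], t_s=t_s, t_sc=t_sc,
            m12=d["m12"], m21=d["m21"],
            nu_anc=1.0, nu_ae=d.get("nu_ae", 1.0), t_ae=d.get("t_ae", 0.0),
            b=b, g=(t_b if with_b else 0.0), t_b=t_b,
        )
        mix = MixtureParams(
            p_island=d.get("p_island", 0.0),
            island_m_factor=d.get("island_m_factor", 1.0),
            q_lowne=d.get("q_lowne", 0.0),
            hrf=d.get("hrf", 1.0),
        )
        return demo, mix

    return names_t, builder


def build_model_catalogue(extended: bool = False) -> list[ModelSpec]:
    """Construct the inference-model catalogue.

    ``extended=False`` gives the 8 basic two-population models (IM, SC and
    their B / AE / AEB variants); ``extended=True`` crosses each with the
    genomic-heterogeneity mixtures (2N, 2M, 2N2M) for 32 models in total.
    """
    specs: list[ModelSpec] = []
    het_variants = [("", False, False)]
    if extended:
        het_variants += [("2N", False, True), ("2M", True, False),
                         ("2N2M", True, True)]
    for gene_flow in ("IM", "SC"):
        for suffix, with_ae, with_b in [("", False, False), ("B", False, True),
                                        ("AE", True, False), ("AEB", True, True)]:
            for het_suffix, het_m, het_n in het_variants:
                names, builder = _two_pop_builder(
                    gene_flow, with_b, with_ae, het_m, het_n)
                specs.append(ModelSpec(
                    name=f"{gene_flow}{suffix}{het_suffix}",
                    family=gene_flow,
                    param_names=names,
                    builder=builder,
                ))
    return specs


# ---------------------------------------------------------------------------
# Simulation scenario grids
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    """One simulated study condition with its ground truth."""

    scenario_id: str
    demography: DemographyParams
    sample_config: SampleConfig
    truth_family: str       # gene-flow scenario that generated the data
    ts_sim: float           # simulated split time (4 N_REF generations)
    tsi_ts_sim: float       # simulated (T_S - T_SC) / T_S


class ScenarioGrid:
    """An ordered collection of uniquely-identified scenarios."""

    def __init__(self, scenarios: Sequence[Scenario]):
        ids = [s.scenario_id for s in scenarios]
        if len(set(ids)) != len(ids):
            raise ValueError("scenario ids must be unique")
        self.scenarios: list[Scenario] = list(scenarios)

    def __len__(self) -> int:
        return len(self.scenarios)

    def __iter__(self) -> Iterator[Scenario]:
        return iter(self.scenarios)

    def __getitem__(self, scenario_id: str) -> Scenario:
        for s in self.scenarios:
            if s.scenario_id == scenario_id:
                return s
        raise KeyError(scenario_id)

    def subset(self, prefix: str) -> "ScenarioGrid":
        return ScenarioGrid([s for s in self.scenarios
                             if s.scenario_id.startswith(prefix)])

    def to_manifest(self, path) -> None:
        """Export the grid as a CSV manifest (one row per scenario)."""
        import pandas as pd

        rows = []
        for s in self.scenarios:
            row = {"scenario_id": s.scenario_id, "truth_family": s.truth_family,
                   "ts_sim": s.ts_sim, "tsi_ts_sim": s.tsi_ts_sim}
            row.update({f"demo_{k}": v for k, v in s.demography.to_dict().items()})
            row.update({f"cfg_{k}": v for k, v in
                        dataclasses.asdict(s.sample_config).items()})
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)

    def to_config(self, path) -> None:
        """Serialise the grid to a plain-text (YAML) configuration file."""
        docs = []
        for s in self.scenarios:
            docs.append({
                "scenario_id": s.scenario_id,
                "truth_family": s.truth_family,
                "ts_sim": s.ts_sim,
                "tsi_ts_sim": s.tsi_ts_sim,
                "demography": s.demography.to_dict(),
                "sample_config": dataclasses.asdict(s.sample_config),
            })
        with open(path, "w") as fh:
            yaml.safe_dump({"scenarios": docs}, fh, sort_keys=False)

    @classmethod
    def from_config(cls, path) -> "ScenarioGrid":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        scenarios = []
        for s in doc["scenarios"]:
            scenarios.append(Scenario(
                scenario_id=s["scenario_id"],
                demography=DemographyParams.from_dict(s["demography"]),
                sample_config=SampleConfig(**s["sample_config"]),
                truth_family=s["truth_family"],
                ts_sim=float(s["ts_sim"]),
                tsi_ts_sim=float(s["tsi_ts_sim"]),
            ))
        return cls(scenarios)


_OLDER_TS = (0.05, 0.1, 0.2, 0.4, 0.8, 1.6)
# eight bottleneck severities in log2 steps; the canonical count of 48
# bottleneck scenarios (6 split times x 8 severities) requires eight levels
_OLDER_B = (0.005, 0.01, 0.02, 0.04, 0.08, 0.16, 0.32, 0.64)
_OLDER_T_EVENT = (0.25, 0.5, 1.0)
_OLDER_ANC_SIZES = (0.25, 1.0 / 16.0, 1.0 / 64.0)


def build_older_grid(
    t_s_values: Sequence[float] = _OLDER_TS,
    bottleneck_b: Sequence[float] = _OLDER_B,
    t_ae_values: Sequence[float] = _OLDER_T_EVENT,
    ae_anc_sizes: Sequence[float] = _OLDER_ANC_SIZES,
    t_ab_values: Sequence[float] = _OLDER_T_EVENT,
    ab_contraction_sizes: Sequence[float] = _OLDER_ANC_SIZES,
    t_b: float = 0.05,
    n_loci: int = 1_000_000,
    n_haploid: int = 20,
) -> ScenarioGrid:
    """Scenario grid for the older divergence scenarios.

    All scenarios are IM with symmetric migration M = 4, ``nu1 = 1`` and
    ``nu2 = 0.25``.  Three sub-grids (select with :meth:`ScenarioGrid.subset`):

    * ``older_base`` / ``older_b``: one baseline per split time plus a recent
      bottleneck in population 2 at ``t_b = 0.05`` followed by exponential
      regrowth to the present (6 + 48 = 54 scenarios);
    * ``older_ae``: ancestral expansions, 6 x 3 x 3 = 54 scenarios;
    * ``older_ab``: ancestral contractions with recovery halfway to the
      split, 6 x 3 x 3 = 54 scenarios.
    """
    cfg = SampleConfig(n1=n_haploid, n2=n_haploid, n_loci=n_loci)
    base = dict(nu1=1.0, nu2=0.25, m12=4.0, m21=4.0, t_sc=0.0)
    scen: list[Scenario] = []

    def add(sid, demo, ts):
        scen.append(Scenario(sid, demo, cfg, "IM", ts, 0.0))

    for ts in t_s_values:
        add(f"older_base_ts{ts:g}", DemographyParams(t_s=ts, **base), ts)
    for ts in t_s_values:
        for b in bottleneck_b:
            demo = DemographyParams(t_s=ts, b=b, t_b=t_b, g=t_b,
                                    nu2_ancient=base["nu2"], **base)
            add(f"older_b_ts{ts:g}_b{b:g}", demo, ts)
    for ts in t_s_values:
        for tae in t_ae_values:
            for anc in ae_anc_sizes:
                demo = DemographyParams(t_s=ts, nu_anc=anc, nu_ae=1.0,
                                        t_ae=tae, **base)
                add(f"older_ae_ts{ts:g}_tae{tae:g}_anc{anc:g}", demo, ts)
    for ts in t_s_values:
        for tab in t_ab_values:
            for contr in ab_contraction_sizes:
                demo = DemographyParams(t_s=ts, nu_anc=1.0, nu_ae=contr,
                                        t_ab=tab, **base)
                add(f"older_ab_ts{ts:g}_tab{tab:g}_sz{contr:g}", demo, ts)
    return ScenarioGrid(scen)


_RECENT_AE = (None, 0.5, 0.25, 0.125, 1.0 / 16, 1.0 / 32, 1.0 / 64, 1.0 / 128)
_RECENT_B = (None, 0.01, 0.02, 0.04, 0.08, 0.16, 0.32, 0.64)
#: exponential regrowth after a founder bottleneck lasts 2,000 generations
RECENT_GROWTH_DURATION = 2_000 / (4.0 * N_REF_DEFAULT)
#: the last ancestral size change sits 0.5 x 4 N_REF generations in the past
ANCESTRAL_EVENT_TIME = 0.5


def build_recent_grid(dataset_size: str = "large") -> ScenarioGrid:
    """The 256-scenario grid of recent divergence histories.

    Fully orthogonal design: {IM (T_S = 0.05), SC (T_S = 0.1, T_SC =
    0.25 T_S)} x {symmetric M = 4, asymmetric m12 = 4 / m21 = 16} x
    {no ancestral expansion, N_ANC = N1/2 ... N1/128 expanding at absolute
    time 0.5} x {no bottleneck, N2 at the split = 1 ... 64 % of its present
    size with 2,000 generations of regrowth}.

    ``dataset_size="large"`` samples 20 haploid genomes per population over
    1e6 loci; ``"small"`` samples 10 over 1e5 loci.
    """
    if dataset_size == "large":
        cfg = SampleConfig(n1=20, n2=20, n_loci=1_000_000)
    elif dataset_size == "small":
        cfg = SampleConfig(n1=10, n2=10, n_loci=100_000)
    else:
        raise ValueError(f"unknown dataset_size {dataset_size!r}")

    scen: list[Scenario] = []
    flows = [("IM", 0.05, 0.0), ("SC", 0.1, 0.025)]
    migs = [("sym", 4.0, 4.0), ("asym", 4.0, 16.0)]
    for family, t_s, t_sc in flows:
        for mig_label, m12, m21 in migs:
            for i_ae, anc in enumerate(_RECENT_AE):
                for i_b, b in enumerate(_RECENT_B):
                    kw = dict(nu1=1.0, nu2=0.25, t_s=t_s, t_sc=t_sc,
                              m12=m12, m21=m21)
                    if anc is not None:
                        kw.update(nu_anc=anc, nu_ae=1.0,
                                  t_ae=ANCESTRAL_EVENT_TIME - t_s)
                    if b is not None:
                        kw.update(b=b, t_b=t_s, g=RECENT_GROWTH_DURATION)
                    sid = f"recent_{family}_{mig_label}_ae{i_ae}_b{i_b}"
                    tsi = 0.0 if family == "IM" else (t_s - t_sc) / t_s
                    scen.append(Scenario(sid, DemographyParams(**kw), cfg,
                                         family, t_s, tsi))
    return ScenarioGrid(scen)
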