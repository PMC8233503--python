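"""Two-population structured-coalescent simulator with infinite-sites
mutation, producing joint allele-frequency spectra.

Time runs backward in units of ``4 * N_REF`` generations: within a deme of
relative size ``x(t)`` every pair of lineages coalesces at rate ``2 / x(t)``
and each lineage in deme *i* jumps to deme *j* at rate ``M_ij``.  At the
split time all lineages merge into the ancestral deme.  Exponential-growth
epochs are handled exactly by closed-form inversion of the integrated
coalescent rate (no discretisation).

With this scaling the per-locus mutation parameter ``theta = 4 N_REF mu L``
is the Poisson intensity of mutations per unit of branch length, so that the
expected number of segregating sites in a panmictic constant-size population
is ``theta * a_{n-1}`` (Watterson).

Only the joint allele-frequency spectrum is of interest downstream, so the
simulator never stores tree topologies for the fast paths: it accumulates,
per genealogy, the total branch length subtending every ``(i, j)`` class of
(pop-1, pop-2) sample counts, and mutation counts are Poisson draws on those
class totals (exact, by Poisson superposition across loci and branches).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .demography import DemographyParams, SampleConfig
from .spectrum import Spectrum

__all__ = [
    "EpochModel",
    "Genealogy",
    "simulate_genealogy",
    "simulate_jafs",
    "expected_branch_jafs",
]

_MAX_POISSON_MEAN = 1e15  # overflow guard for pathological theta
# per-genealogy event budget: generous (typical histories need < 10^2 events)
# but bounds the cost of migration-dominated corners of parameter space
_MAX_EVENTS = 200_000


@dataclass(frozen=True)
class EpochModel:
    """Piecewise-exponential backward-time demography compiled to arrays.

    Epoch ``e`` spans ``[t_start[e], t_start[e+1])`` (the last epoch is open
    and must be size-constant).  Within an epoch the size of deme ``d`` is
    ``x_d(t) = x_d[e] * exp(r_d[e] * (t - t_start[e]))``.  ``two[e]`` flags
    whether deme 1 still exists; the first epoch with ``two == 0`` absorbs
    all deme-1 lineages (the population split, seen backward).
    """

    t_start: np.ndarray
    x0: np.ndarray
    r0: np.ndarray
    x1: np.ndarray
    r1: np.ndarray
    m01: np.ndarray
    m10: np.ndarray
    two: np.ndarray

    def __post_init__(self):
        E = len(self.t_start)
        for name in ("x0", "r0", "x1", "r1", "m01", "m10", "two"):
            if len(getattr(self, name)) != E:
                raise ValueError("epoch arrays must have equal length")
        if self.r0[-1] != 0.0 or self.two[-1] != 0:
            raise ValueError("final epoch must be constant and single-deme")

    @classmethod
    def from_demography(cls, demo: DemographyParams,
                        mig_scale: float = 1.0,
                        size_scale: float = 1.0) -> "EpochModel":
        """Compile a :class:`DemographyParams` into epochs.

        ``mig_scale`` multiplies both migration rates and ``size_scale``
        multiplies every population size; the genomic-heterogeneity mixture
        classes of the inference models are built this way.
        """
        ts, tsc = demo.t_s, demo.t_sc
        bps = {0.0}
        if ts > 0:
            bps.add(ts)
        grow = demo.b < 1.0 and demo.g > 0.0
        tb = demo.t_b if demo.t_b is not None else ts
        if demo.b < 1.0:
            if tb - demo.g > 0:
                bps.add(tb - demo.g)
            if tb < ts:
                bps.add(tb)
        if tsc > 0.0:
            bps.add(tsc)
        if demo.t_ae > 0.0:
            bps.add(ts + demo.t_ae)
        if demo.t_ab > 0.0:
            bps.add(ts + demo.t_ab / 2.0)
            bps.add(ts + demo.t_ab)
        cuts = sorted(bps)
        # drop breakpoints that collide numerically
        uniq = [cuts[0]]
        for c in cuts[1:]:
            if c - uniq[-1] > 1e-13:
                uniq.append(c)
        cuts = uniq

        def size2(t: float) -> float:
            if demo.b < 1.0:
                lo = tb - demo.g
                if t >= tb:
                    anc = demo.nu2_ancient
                    return anc if anc is not None else demo.b * demo.nu2
                if t >= lo and demo.g > 0:
                    return demo.nu2 * demo.b ** ((t - lo) / demo.g)
            return demo.nu2

        def size_anc(t: float) -> float:
            if demo.t_ae > 0.0:
                return demo.nu_ae if t < ts + demo.t_ae else demo.nu_anc
            if demo.t_ab > 0.0:
                if t < ts + demo.t_ab / 2.0:
                    return demo.nu_anc
                if t < ts + demo.t_ab:
                    return demo.nu_ae
            return demo.nu_anc

        E = len(cuts)
        t0 = np.array(cuts)
        x0 = np.empty(E)
        r0 = np.zeros(E)
        x1 = np.ones(E)
        r1 = np.zeros(E)
        m01 = np.zeros(E)
        m10 = np.zeros(E)
        two = np.zeros(E, dtype=np.uint8)
        gr_rate = np.log(demo.b) / demo.g if grow else 0.0
        for e, a in enumerate(cuts):
            if a < ts:
                two[e] = 1
                x0[e] = demo.nu1
                x1[e] = size2(a)
                if grow and (tb - demo.g) - 1e-13 <= a < tb - 1e-13:
                    r1[e] = gr_rate
                migrating = (tsc == 0.0) or (a < tsc)
                if migrating:
                    m01[e] = demo.m12 * mig_scale
                    m10[e] = demo.m21 * mig_scale
            else:
                x0[e] = size_anc(a)
        x0 *= size_scale
        x1 *= size_scale
        return cls(t0, x0, r0, x1, r1, m01, m10, two)

    @classmethod
    def one_population(cls, t_bounds, x_start, x_end=None,
                       size_scale: float = 1.0) -> "EpochModel":
        """Single-deme piecewise-exponential history.

        ``t_bounds`` are epoch start times (beginning with 0); epoch ``e``
        interpolates exponentially from ``x_start[e]`` at its start to
        ``x_end[e]`` at its end (constant if ``x_end`` is None or equal).
        The last epoch is constant at ``x_start[-1]``.
        """
        t0 = np.asarray(t_bounds, dtype=float)
        xs = np.asarray(x_start, dtype=float) * size_scale
        E = len(t0)
        r0 = np.zeros(E)
        if x_end is not None:
            xe = np.asarray(x_end, dtype=float) * size_scale
            for e in range(E - 1):
                span = t0[e + 1] - t0[e]
                if span > 0 and xe[e] != xs[e]:
                    r0[e] = np.log(xe[e] / xs[e]) / span
        return cls(t0, xs, r0, np.ones(E), np.zeros(E), np.zeros(E),
                   np.zeros(E), np.zeros(E, dtype=np.uint8))

    def arrays(self):
        return (self.t_start, self.x0, self.r0, self.x1, self.r1,
                self.m01, self.m10, self.two)


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _coal_wait(k, x_epoch_start, rate, elapsed):
    """Waiting time to the next coalescence among k lineages in a deme whose
    size is x_epoch_start * exp(rate * (elapsed + tau)).  Draws its own
    Exp(1) variate; exact for exponential growth by inverting the
    integrated pair-coalescence rate."""
    if k < 2:
        return np.inf
    A = k * (k - 1.0)
    u = -np.log(np.random.random())
    if rate == 0.0:
        return u * x_epoch_start / A
    x_now = x_epoch_start * np.exp(rate * elapsed)
    arg = 1.0 - u * rate * x_now / A
    if arg <= 0.0:
        return np.inf
    return -np.log(arg) / rate


@njit(cache=True, fastmath=True)
def _sim_class_times(t0, x0, r0, x1, r1, m01, m10, two,
                     n1, n2, n_reps, seed):
    """Accumulate, over ``n_reps`` independent genealogies, the total branch
    length subtending each (i, j) class of sample counts."""
    np.random.seed(seed)
    E = t0.shape[0]
    T = np.zeros((n1 + 1, n2 + 1))
    N = n1 + n2
    deme = np.empty(N, np.int64)
    di = np.empty(N, np.int64)
    dj = np.empty(N, np.int64)
    for _ in range(n_reps):
        for l in range(n1):
            deme[l] = 0
            di[l] = 1
            dj[l] = 0
        for l in range(n2):
            deme[n1 + l] = 1
            di[n1 + l] = 0
            dj[n1 + l] = 1
        if two[0] == 0:
            for l in range(N):
                deme[l] = 0
        k = N
        t = 0.0
        e = 0
        n_events = 0
        while k > 1:
            n_events += 1
            if n_events > _MAX_EVENTS:
                T[0, 0] = np.nan
                return T
            t_end = t0[e + 1] if e + 1 < E else np.inf
            k0 = 0
            for l in range(k):
                if deme[l] == 0:
                    k0 += 1
            k1 = k - k0
            el = t - t0[e]
            w0 = _coal_wait(k0, x0[e], r0[e], el)
            if two[e] == 1:
                w1 = _coal_wait(k1, x1[e], r1[e], el)
                Rm = k0 * m01[e] + k1 * m10[e]
                wm = -np.log(np.random.random()) / Rm if Rm > 0.0 else np.inf
            else:
                w1 = np.inf
                wm = np.inf
                Rm = 0.0
            w = w0
            ev = 0
            if w1 < w:
                w = w1
                ev = 1
            if wm < w:
                w = wm
                ev = 2
            if t + w >= t_end:
                dt = t_end - t
                for l in range(k):
                    T[di[l], dj[l]] += dt
                t = t_end
                e += 1
                if two[e] == 0 and two[e - 1] == 1:
                    for l in range(k):
                        deme[l] = 0
                continue
            for l in range(k):
                T[di[l], dj[l]] += w
            t += w
            if ev == 2:
                # migration: choose a lineage proportionally to its rate
                r = np.random.random() * Rm
                acc = 0.0
                idx = k - 1
                for l in range(k):
                    acc += m01[e] if deme[l] == 0 else m10[e]
                    if acc >= r:
                        idx = l
                        break
                deme[idx] = 1 - deme[idx]
            else:
                d = ev
                kd = k0 if d == 0 else k1
                a = int(np.random.random() * kd)
                b = int(np.random.random() * (kd - 1))
                if b >= a:
                    b += 1
                if a > b:
                    a, b = b, a
                ia = -1
                ib = -1
                cnt = 0
                for l in range(k):
                    if deme[l] == d:
                        if cnt == a:
                            ia = l
                        if cnt == b:
                            ib = l
                            break
                        cnt += 1
                di[ia] += di[ib]
                dj[ia] += dj[ib]
                k -= 1
                deme[ib] = deme[k]
                di[ib] = di[k]
                dj[ib] = dj[k]
    return T


@njit(cache=True, fastmath=True)
def _sim_thinned_jafs(t0, x0, r0, x1, r1, m01, m10, two,
                      n1, n2, n_loci, theta, seed):
    """One-SNP-per-locus jAFS: for every locus, the locus is polymorphic
    with probability 1 - exp(-theta * L_tree) and contributes one SNP whose
    (i, j) cell is drawn proportionally to the class branch lengths."""
    np.random.seed(seed)
    E = t0.shape[0]
    counts = np.zeros((n1 + 1, n2 + 1))
    Tl = np.zeros((n1 + 1, n2 + 1))
    N = n1 + n2
    deme = np.empty(N, np.int64)
    di = np.empty(N, np.int64)
    dj = np.empty(N, np.int64)
    for _ in range(n_loci):
        for i in range(n1 + 1):
            for j in range(n2 + 1):
                Tl[i, j] = 0.0
        for l in range(n1):
            deme[l] = 0
            di[l] = 1
            dj[l] = 0
        for l in range(n2):
            deme[n1 + l] = 1
            di[n1 + l] = 0
            dj[n1 + l] = 1
        if two[0] == 0:
            for l in range(N):
                deme[l] = 0
        k = N
        t = 0.0
        e = 0
        ltot = 0.0
        n_events = 0
        while k > 1:
            n_events += 1
            if n_events > _MAX_EVENTS:
                counts[0, 0] = np.nan
                return counts
            t_end = t0[e + 1] if e + 1 < E else np.inf
            k0 = 0
            for l in range(k):
                if deme[l] == 0:
                    k0 += 1
            k1 = k - k0
            el = t - t0[e]
            w0 = _coal_wait(k0, x0[e], r0[e], el)
            if two[e] == 1:
                w1 = _coal_wait(k1, x1[e], r1[e], el)
                Rm = k0 * m01[e] + k1 * m10[e]
                wm = -np.log(np.random.random()) / Rm if Rm > 0.0 else np.inf
            else:
                w1 = np.inf
                wm = np.inf
                Rm = 0.0
            w = w0
            ev = 0
            if w1 < w:
                w = w1
                ev = 1
            if wm < w:
                w = wm
                ev = 2
            if t + w >= t_end:
                dt = t_end - t
                for l in range(k):
                    Tl[di[l], dj[l]] += dt
                ltot += k * dt
                t = t_end
                e += 1
                if two[e] == 0 and two[e - 1] == 1:
                    for l in range(k):
                        deme[l] = 0
                continue
            for l in range(k):
                Tl[di[l], dj[l]] += w
            ltot += k * w
            t += w
            if ev == 2:
                r = np.random.random() * Rm
                acc = 0.0
                idx = k - 1
                for l in range(k):
                    acc += m01[e] if deme[l] == 0 else m10[e]
                    if acc >= r:
                        idx = l
                        break
                deme[idx] = 1 - deme[idx]
            else:
                d = ev
                kd = k0 if d == 0 else k1
                a = int(np.random.random() * kd)
                b = int(np.random.random() * (kd - 1))
                if b >= a:
                    b += 1
                if a > b:
                    a, b = b, a
                ia = -1
                ib = -1
                cnt = 0
                for l in range(k):
                    if deme[l] == d:
                        if cnt == a:
                            ia = l
                        if cnt == b:
                            ib = l
                            break
                        cnt += 1
                di[ia] += di[ib]
                dj[ia] += dj[ib]
                k -= 1
                deme[ib] = deme[k]
                di[ib] = di[k]
                dj[ib] = dj[k]
        # mutation stage: keep one random SNP if the locus is polymorphic
        if np.random.random() < 1.0 - np.exp(-theta * ltot):
            r = np.random.random() * ltot
            acc = 0.0
            done = False
            for i in range(n1 + 1):
                if done:
                    break
                for j in range(n2 + 1):
                    acc += Tl[i, j]
                    if acc >= r:
                        counts[i, j] += 1.0
                        done = True
                        break
    return counts


def _kernel_seed(seed: int, salt: int = 0) -> int:
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, salt])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def class_branch_lengths(epochs: EpochModel, n1: int, n2: int,
                         n_reps: int, seed: int) -> np.ndarray:
    """Total subtended branch length per (i, j) class, summed over
    ``n_reps`` independent genealogies (units of 4 N_REF generations)."""
    if n1 + n2 < 2:
        raise ValueError("need at least two sampled lineages in total")
    T = _sim_class_times(*epochs.arrays(), n1, n2, int(n_reps),
                         _kernel_seed(seed))
    if np.isnan(T[0, 0]):
        raise ValueError("genealogy exceeded the event budget "
                         "(migration-dominated history)")
    return T


# ---------------------------------------------------------------------------
# public simulation API
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Genealogy:
    """A coalescent genealogy reduced to its branch classes.

    Each branch carries its length (units of 4 N_REF generations) and the
    number of sampled lineages from populations 1 and 2 it subtends.
    """

    branches: tuple[tuple[float, int, int], ...]
    tmrca: float
    n1: int
    n2: int

    def class_lengths(self) -> np.ndarray:
        T = np.zeros((self.n1 + 1, self.n2 + 1))
        for length, i, j in self.branches:
            T[i, j] += length
        return T


def simulate_genealogy(demo: DemographyParams, n1: int, n2: int,
                       seed: int) -> Genealogy:
    """Simulate one genealogy, branch by branch (readable reference path).

    This is the pure-Python counterpart of the batch kernel: an event-driven
    structured coalescent over the same compiled epochs, retaining each
    branch's length and subtended sample counts.
    """
    if n1 + n2 < 2:
        raise ValueError("need at least two sampled lineages in total")
    if n1 < 0 or n2 < 0:
        raise ValueError("sample sizes must be non-negative")
    # a split at time zero collapses both samples into the ancestral deme
    epochs = EpochModel.from_demography(demo)
    rng = np.random.default_rng(seed)
    t0, x0, r0, x1, r1, m01, m10, two = epochs.arrays()
    E = len(t0)

    lineages = [[0, 1, 0, 0.0] for _ in range(n1)] + \
               [[1, 0, 1, 0.0] for _ in range(n2)]  # deme, i, j, birth time
    if two[0] == 0:
        for lin in lineages:
            lin[0] = 0
    branches: list[tuple[float, int, int]] = []
    t, e = 0.0, 0

    def coal_wait(k, xs, rate, elapsed):
        if k < 2:
            return np.inf
        A = k * (k - 1.0)
        x_now = xs * np.exp(rate * elapsed)
        u = rng.exponential()
        if rate == 0.0:
            return u * x_now / A
        arg = 1.0 - u * rate * x_now / A
        return np.inf if arg <= 0.0 else -np.log(arg) / rate

    while len(lineages) > 1:
        t_end = t0[e + 1] if e + 1 < E else np.inf
        idx0 = [i for i, l in enumerate(lineages) if l[0] == 0]
        idx1 = [i for i, l in enumerate(lineages) if l[0] == 1]
        el = t - t0[e]
        w0 = coal_wait(len(idx0), x0[e], r0[e], el)
        if two[e]:
            w1 = coal_wait(len(idx1), x1[e], r1[e], el)
            Rm = len(idx0) * m01[e] + len(idx1) * m10[e]
            wm = rng.exponential() / Rm if Rm > 0 else np.inf
        else:
            w1, wm, Rm = np.inf, np.inf, 0.0
        w, ev = min((w0, 0), (w1, 1), (wm, 2))
        if t + w >= t_end:
            t = t_end
            e += 1
            if two[e] == 0 and two[e - 1] == 1:
                for lin in lineages:
                    lin[0] = 0
            continue
        t += w
        if ev == 2:
            weights = np.array([m01[e] if l[0] == 0 else m10[e]
                                for l in lineages])
            idx = rng.choice(len(lineages), p=weights / weights.sum())
            lineages[idx][0] = 1 - lineages[idx][0]
        else:
            group = idx0 if ev == 0 else idx1
            a, b = rng.choice(len(group), size=2, replace=False)
            ia, ib = group[a], group[b]
            la, lb = lineages[ia], lineages[ib]
            for lin in (la, lb):
                branches.append((t - lin[3], lin[1], lin[2]))
            la[1] += lb[1]
            la[2] += lb[2]
            la[3] = t
            del lineages[ib]
    return Genealogy(tuple(branches), tmrca=t, n1=n1, n2=n2)


def expected_branch_jafs(demo: DemographyParams, n1: int, n2: int,
                         n_reps: int, seed: int) -> Spectrum:
    """Monte-Carlo expectation of the branch-length jAFS (density mode).

    Cell ``(i, j)`` holds the mean total branch length subtending ``i``
    samples from population 1 and ``j`` from population 2, so that
    ``theta_locus * cell`` is the expected per-locus mutation count in that
    cell.  Deterministic given the seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    epochs = EpochModel.from_demography(demo)
    T = class_branch_lengths(epochs, n1, n2, n_reps, seed)
    return Spectrum(T / n_reps)


def jafs_from_epochs(epochs: EpochModel, n1: int, n2: int,
                     n_reps: int, seed: int) -> Spectrum:
    """Branch-expectation spectrum for an already compiled epoch model."""
    T = class_branch_lengths(epochs, n1, n2, n_reps, seed)
    return Spectrum(T / n_reps)


def simulate_jafs(demo: DemographyParams, cfg: SampleConfig, seed: int,
                  folded: bool = False,
                  max_snps_per_locus: int | None = 1) -> Spectrum:
    """Simulate an observed jAFS from ``cfg.n_loci`` unlinked loci with
    infinite-sites mutations at per-locus intensity ``theta = 4 N_REF mu L``.

    By default (``max_snps_per_locus=1``) each polymorphic locus contributes
    a single randomly chosen SNP, so every entry of the spectrum is an
    independent, unlinked site -- the convention of short-tag (RAD-style)
    data sets and the assumption behind the composite likelihood downstream.

    With ``max_snps_per_locus=None`` every mutation is kept.  Loci being
    independent and mutation counts conditionally Poisson, the total count
    per (i, j) cell is then drawn as a single Poisson with mean ``theta``
    times the class branch length summed over loci -- exactly the
    distribution of summing per-branch Poisson draws locus by locus.
    """
    epochs = EpochModel.from_demography(demo)
    if max_snps_per_locus == 1:
        counts = _sim_thinned_jafs(*epochs.arrays(), cfg.n1, cfg.n2,
                                   int(cfg.n_loci), cfg.theta_locus,
                                   _kernel_seed(seed))
        if np.isnan(counts[0, 0]):
            raise ValueError("genealogy exceeded the event budget "
                             "(migration-dominated history)")
    elif max_snps_per_locus is None:
        T = class_branch_lengths(epochs, cfg.n1, cfg.n2, cfg.n_loci, seed)
        lam = cfg.theta_locus * T
        if np.any(lam > _MAX_POISSON_MEAN):
            raise OverflowError("per-cell mutation intensity too large; "
                                "check theta and locus count")
        rng = np.random.default_rng(np.random.SeedSequence(
            [int(seed) & 0x7FFFFFFF, 0x6D75]))
        counts = rng.poisson(lam).astype(float)
    else:
        raise ValueError("max_snps_per_locus must be 1 or None")
    afs = Spectrum(counts)
    return afs.fold() if folded else afs
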