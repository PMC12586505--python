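"""Forward-time Monte Carlo of a finite ensemble of finite tribes.

Each of ``M`` tribes holds exactly ``N_eq`` reproductive individuals
(the analytics condition on the stationary expected population, so the
simulator keeps tribe size fixed, Moran style, and carries no
demographic noise).  Per discrete time step of length ``step`` years:

1. every individual exits with probability ``step / tau_E`` and is
   replaced by the Mendelian offspring of a uniformly random ordered
   pair of distinct surviving tribe members (sexes are not tracked:
   with exact female-male parity and random mating the offspring
   genotype law is unchanged);
2. tribes exchange individuals with their environment.  In the
   analytic model this exchange cancels out of the genotype equations
   identically -- its entire role is the assumption that each tribe
   stays a representative sample of the ensemble.  The default
   ``bath_ratio = inf`` realizes that assumption exactly: after each
   step all individuals are randomly permuted across tribes (genotype
   totals conserved, ensemble mean untouched), so a tribe at any
   observation is a random partition cell of the pooled ensemble and
   the binomial/multinomial tribe-count laws hold.  A finite
   ``bath_ratio`` instead swaps each individual at rate
   ``bath_ratio / tau_E`` for a draw from a pool matching the ensemble
   genotype frequencies (balanced composition, so the ensemble mean
   does not random-walk); this leaves a residual kin correlation
   between tribe-mates born locally since their tribe's last exchange,
   visible as 15-30% over-dispersion of tribe counts at
   ``bath_ratio ~ 3``.  With ``bath_ratio = 0`` tribes are
   genealogically isolated and within-tribe drift accumulates far
   beyond the binomial dispersion (the classical drift regime the
   analytics deliberately do not describe).

Every ``delta_t`` years an immigration cycle replaces a random subset
of each tribe with immigrant homozygotes (at all loci).  The number of
immigrants per tribe is Binomial(N_eq, chi) by default, so the
ensemble-average replaced fraction is exactly chi (the quantity the
closed forms are written in) even when chi * N_eq is not an integer;
``immigrants="exact"`` replaces round(chi * N_eq) individuals instead.

Loci are simulated as statistically independent: each locus draws its
own parental alleles.  Genotypes are coded by immigrant-allele count,
0 = resident homozygote, 1 = heterozygote, 2 = immigrant homozygote.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .ensemble import TribeEnsemble
from .genotypes import GenotypeDistribution

__all__ = ["SimConfig", "SimResult", "simulate_ensemble", "relaxation_experiment"]

#: default tribe-bath exchange: infinitely fast mixing, i.e. every tribe
#: is a representative sample of the pooled ensemble at all times
DEFAULT_BATH_RATIO = math.inf


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one ensemble simulation.

    Parameters
    ----------
    n_eq : int
        Reproductive individuals per tribe (held fixed).
    m_tribes : int
        Number of independent tribes in the ensemble.
    tau_e : float
        Exit mean lifetime in years (1 / k_E).
    chi : float
        Ensemble-average immigrant fraction per cycle, in [0, 1].
    delta_t : float
        Years between immigration cycles.
    n_cycles : int
        Number of immigration cycles (also sets the total duration
        n_cycles * delta_t for runs without immigration).
    seed : int
        Mandatory RNG seed; identical configs give bit-identical output.
    step : float, optional
        Event-time discretization in years; defaults to tau_e / 20 and
        may not exceed it (keeps the geometric exit process within a
        few percent of the exponential).
    n_loci : int
        Independent loci carried per individual.
    immigrants : {"binomial", "exact"}
        Per-cycle immigrant count law (see module docstring).
    bath_ratio : float
        Tribe-bath exchange ratio gamma / k_E.  ``inf`` (default) is the
        well-mixed idealization under which the analytic tribe-count
        laws hold; 0 disables exchange entirely (isolated tribes).
    """

    n_eq: int
    m_tribes: int
    tau_e: float
    chi: float
    delta_t: float
    n_cycles: int
    seed: int
    step: float | None = None
    n_loci: int = 1
    immigrants: Literal["binomial", "exact"] = "binomial"
    bath_ratio: float = DEFAULT_BATH_RATIO

    def __post_init__(self) -> None:
        if self.n_eq < 2:
            raise ValueError("n_eq must be at least 2")
        if self.m_tribes < 1:
            raise ValueError("m_tribes must be at least 1")
        if self.tau_e <= 0:
            raise ValueError("tau_e must be positive")
        if not 0 <= self.chi <= 1:
            raise ValueError("chi must lie in [0, 1]")
        if self.delta_t <= 0:
            raise ValueError("delta_t must be positive")
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be non-negative")
        if self.seed is None or int(self.seed) != self.seed:
            raise ValueError("an integer seed is mandatory")
        if self.step is not None and not 0 < self.step <= self.tau_e / 20.0:
            raise ValueError("step must lie in (0, tau_e / 20]")
        if self.n_loci < 1:
            raise ValueError("n_loci must be at least 1")
        if self.immigrants not in ("binomial", "exact"):
            raise ValueError("immigrants must be 'binomial' or 'exact'")
        if self.bath_ratio < 0:
            raise ValueError("bath_ratio must be non-negative")

    @property
    def effective_step(self) -> float:
        """Step actually used: an integer divisor of delta_t, <= tau_e/20."""
        target = self.step if self.step is not None else self.tau_e / 20.0
        n_steps = max(1, int(np.ceil(self.delta_t / target - 1e-12)))
        return self.delta_t / n_steps


@dataclass(frozen=True)
class SimResult:
    """Output of one ensemble simulation.

    ``times``/``mean_probs`` sample the ensemble-mean genotype
    probabilities (columns P_N, P_S, P_NS, averaged over tribes and
    loci) at every step.  ``cycle_times``/``cycle_counts`` hold the
    per-tribe genotype counts at t = 0 and at each cycle end (just
    before the next perturbation); ``cycle_counts`` has shape
    (n_records, M, n_loci, 3) in genotype-code order (NN, NS, SS).
    """

    config: SimConfig
    times: np.ndarray = field(repr=False)
    mean_probs: np.ndarray = field(repr=False)
    cycle_times: np.ndarray = field(repr=False)
    cycle_counts: np.ndarray = field(repr=False)

    @property
    def cycle_mean_probs(self) -> np.ndarray:
        """Ensemble-mean (P_N, P_S, P_NS) at each recorded cycle end."""
        c = self.cycle_counts.mean(axis=(1, 2)) / self.config.n_eq
        return np.stack([c[:, 0], c[:, 2], c[:, 1]], axis=1)

    def final_ensemble(self, locus: int = 0) -> TribeEnsemble:
        """Final per-tribe counts at one locus as a TribeEnsemble."""
        c = self.cycle_counts[-1, :, locus, :]  # (M, 3) in (NN, NS, SS)
        return TribeEnsemble(
            n_eq=self.config.n_eq,
            counts=np.stack([c[:, 2], c[:, 0], c[:, 1]], axis=1),
        )

    def mean_probs_at(self, t: float) -> np.ndarray:
        """Ensemble-mean probabilities at the step time closest to t."""
        idx = int(np.argmin(np.abs(self.times - t)))
        return self.mean_probs[idx]


def _genotype_counts(geno: np.ndarray) -> np.ndarray:
    """Per-tribe per-locus genotype counts, shape (M, L, 3) in code order."""
    return np.stack([(geno == g).sum(axis=1) for g in (0, 1, 2)], axis=-1)


def _mean_probs(geno: np.ndarray) -> np.ndarray:
    """Ensemble-mean (P_N, P_S, P_NS) over all tribes and loci."""
    frac = np.array([(geno == g).mean() for g in (0, 1, 2)])
    return np.array([frac[0], frac[2], frac[1]])


def _reproduction_step(
    geno: np.ndarray, p_exit: float, rng: np.random.Generator
) -> np.ndarray:
    """Exit-and-replace: Moran-style turnover with Mendelian offspring."""
    m, n, _l = geno.shape
    exit_mask = rng.random((m, n)) < p_exit
    if not exit_mask.any():
        return geno
    n_surv = n - exit_mask.sum(axis=1)
    # stable sort puts survivors (False) first; with fewer than two
    # survivors fall back to sampling parents from the full tribe
    order = np.argsort(exit_mask, axis=1, kind="stable")
    bound = np.where(n_surv >= 2, n_surv, n)[:, None]
    u1 = (rng.random((m, n)) * bound).astype(np.intp)
    u2 = (rng.random((m, n)) * (bound - 1)).astype(np.intp)
    u2 += u2 >= u1  # ordered pair of distinct individuals
    p1 = np.take_along_axis(order, u1, axis=1)[:, :, None]
    p2 = np.take_along_axis(order, u2, axis=1)[:, :, None]
    g1 = np.take_along_axis(geno, p1, axis=1)
    g2 = np.take_along_axis(geno, p2, axis=1)
    # one allele from each parent, independently per locus
    a1 = rng.random(geno.shape) < 0.5 * g1
    a2 = rng.random(geno.shape) < 0.5 * g2
    offspring = a1.astype(np.int8) + a2.astype(np.int8)
    return np.where(exit_mask[:, :, None], offspring, geno)


def _balanced_pool(counts: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k genotypes whose composition matches ``counts`` proportions exactly.

    Largest-remainder rounding of k * counts / counts.sum(), shuffled.
    """
    target = counts * (k / counts.sum())
    base = np.floor(target).astype(np.int64)
    short = k - int(base.sum())
    if short > 0:
        base[np.argsort(target - base)[::-1][:short]] += 1
    pool = np.repeat(np.arange(3, dtype=np.int8), base)
    rng.shuffle(pool)
    return pool


def _bath_exchange_step(
    geno: np.ndarray, p_exch: float, rng: np.random.Generator
) -> np.ndarray:
    """Swap individuals for bath draws at the ensemble genotype frequencies.

    The bath stands for the infinite tribe ensemble, whose genotype
    distribution equals the expected-population one; with M simulated
    tribes the best available stand-in is the current ensemble
    frequency.  The swapped-in pool composition matches that frequency
    exactly (largest-remainder rounding), so the exchange redistributes
    genotypes among tribes without moving the ensemble mean: a naive
    per-individual multinomial draw would make the mean itself perform
    a random walk of scale sqrt(t / (M N_eq)), which is an artifact of
    the finite ensemble standing in for an infinite one.
    """
    m, n, n_loci = geno.shape
    swap = rng.random((m, n)) < p_exch
    k = int(swap.sum())
    if k == 0:
        return geno
    geno = geno.copy()
    for locus in range(n_loci):
        plane = geno[:, :, locus]
        counts = np.bincount(plane.ravel(), minlength=3)
        plane[swap] = _balanced_pool(counts, k, rng)
    return geno


def _well_mixed_step(geno: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Randomly permute whole individuals across tribes.

    The infinitely-fast-exchange idealization: every tribe is at all
    times a random partition cell of the pooled ensemble.  Genotype
    totals (hence the ensemble mean) are conserved exactly; the
    permutation moves individuals, so cross-locus genotype combinations
    stay intact.
    """
    m, n, n_loci = geno.shape
    flat = geno.reshape(m * n, n_loci)
    return flat[rng.permutation(m * n)].reshape(m, n, n_loci)


def _immigration_event(
    geno: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Replace a random subset of each tribe with immigrant homozygotes."""
    m, n, _l = geno.shape
    if config.immigrants == "binomial":
        n_imm = rng.binomial(n, config.chi, size=m)
    else:
        n_imm = np.full(m, int(round(config.chi * n)))
    if not n_imm.any():
        return geno
    ranks = rng.random((m, n)).argsort(axis=1).argsort(axis=1)
    mask = ranks < n_imm[:, None]
    geno = geno.copy()
    geno[mask] = 2  # immigrant homozygote at every locus
    return geno


def _run(
    geno: np.ndarray, config: SimConfig, rng: np.random.Generator, immigrate: bool
) -> SimResult:
    dt = config.effective_step
    steps_per_cycle = int(round(config.delta_t / dt))
    p_exit = dt / config.tau_e
    well_mixed = math.isinf(config.bath_ratio)
    p_exch = 0.0 if well_mixed else config.bath_ratio * dt / config.tau_e

    times = [0.0]
    mean_probs = [_mean_probs(geno)]
    cycle_times = [0.0]
    cycle_counts = [_genotype_counts(geno)]

    t = 0.0
    for _cycle in range(config.n_cycles):
        if immigrate and config.chi > 0:
            geno = _immigration_event(geno, config, rng)
        for _ in range(steps_per_cycle):
            geno = _reproduction_step(geno, p_exit, rng)
            if well_mixed and config.m_tribes > 1:
                geno = _well_mixed_step(geno, rng)
            elif p_exch > 0:
                geno = _bath_exchange_step(geno, p_exch, rng)
            t += dt
            times.append(t)
            mean_probs.append(_mean_probs(geno))
        cycle_times.append(t)
        cycle_counts.append(_genotype_counts(geno))

    return SimResult(
        config=config,
        times=np.asarray(times),
        mean_probs=np.asarray(mean_probs),
        cycle_times=np.asarray(cycle_times),
        cycle_counts=np.asarray(cycle_counts, dtype=np.int64),
    )


def simulate_ensemble(config: SimConfig) -> SimResult:
    """Simulate immigration cycles into initially pure-resident tribes.

    Every tribe starts as N_eq resident homozygotes at every locus; each
    cycle applies the immigration perturbation and then relaxes for
    delta_t years.  Cycle-end records are taken after relaxation, so
    ``cycle_mean_probs[j]`` is directly comparable to the analytic
    post-relaxation equilibrium after j cycles.
    """
    rng = np.random.default_rng(config.seed)
    geno = np.zeros((config.m_tribes, config.n_eq, config.n_loci), dtype=np.int8)
    return _run(geno, config, rng, immigrate=True)


def relaxation_experiment(config: SimConfig, init: GenotypeDistribution) -> SimResult:
    """Free relaxation (no immigration) from a sampled initial distribution.

    Each tribe's initial genotype counts are drawn multinomially from
    ``init`` at every locus; the ensemble then relaxes for
    n_cycles * delta_t years.  Validates the closed-form genotype
    trajectory and the invariance of P_N - P_S.
    """
    if config.chi != 0:
        raise ValueError("relaxation_experiment requires chi = 0")
    rng = np.random.default_rng(config.seed)
    m, n, l = config.m_tribes, config.n_eq, config.n_loci
    probs = [init.p_n, init.p_ns, init.p_s]  # genotype-code order
    geno = np.empty((m, n, l), dtype=np.int8)
    for i in range(m):
        for j in range(l):
            counts = rng.multinomial(n, probs)
            geno[i, :, j] = np.repeat(np.int8([0, 1, 2]), counts)
    return _run(geno, config, rng, immigrate=False)
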