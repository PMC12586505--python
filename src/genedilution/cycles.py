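"""Recurrent immigration cycles and dilution-time calculators.

Each immigration cycle instantaneously replaces a fraction ``chi`` of
the stationary tribe population with immigrant (H. sapiens) homozygotes;
the genotype distribution then relaxes to its new equilibrium before the
next cycle (valid when the inter-cycle interval exceeds ~2 exit
lifetimes).  The conserved difference obeys the affine recursion

    delta_P_{0,j} = delta_P_{0,j-1} (1 - chi) - chi
                  = (1 - chi)**j (1 + delta_P_{0,0}) - 1,

and, starting from a pure-resident population (delta_P_{0,0} = 1), the
post-relaxation equilibrium genotype probabilities after j cycles are

    P_N,j = (1 - chi)**(2j),
    P_S,j = ((1 - chi)**j - 1)**2,
    P_NS,j = (1 - (2 (1 - chi)**j - 1)**2) / 2.

The implied allele frequencies, p_j = 1 - (1 - chi)**j for the immigrant
allele and q_j = (1 - chi)**j for the resident allele, coincide with the
classical continent-island recursion: that model's allele dynamics are
recovered as a special case of the genotype-level framework.

The number of cycles needed to push the immigrant-homozygote probability
to a target ``P_Sf`` is

    J_f = ln(1 - sqrt(P_Sf)) / ln(1 - chi),

and the total dilution time is T_f = J_f * delta_t.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeDistribution, equilibrium_distribution

__all__ = [
    "CycleSchedule",
    "apply_cycle",
    "delta_p_after_cycles",
    "subgroup_probs_after_cycles",
    "allele_frequencies",
    "cycles_to_target",
    "whole_cycles_to_target",
    "total_time",
    "chi_for_time",
    "iterate_cycles",
]

# perturbation-size advisory threshold: the closed forms assume small
# per-cycle genetic perturbations, chi <~ 2/30
SMALL_PERTURBATION_CHI = 2.0 / 30.0


@dataclass(frozen=True)
class CycleSchedule:
    """An immigration schedule: per-cycle fraction and cycle spacing.

    Parameters
    ----------
    chi : float
        Ensemble-average immigrant fraction per cycle, in (0, 1).
    delta_t : float
        Mean interval between cycles, years.
    delta_p00 : float, default 1
        Conserved difference before any cycle; 1 corresponds to an
        initially pure-resident population.
    """

    chi: float
    delta_t: float
    delta_p00: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.chi < 1:
            raise ValueError("chi must lie in (0, 1)")
        if self.delta_t <= 0:
            raise ValueError("delta_t must be positive")
        if abs(self.delta_p00) > 1:
            raise ValueError("|delta_p00| must not exceed 1")
        if self.chi > SMALL_PERTURBATION_CHI:
            warnings.warn(
                f"chi = {self.chi:.4g} exceeds the small-perturbation regime "
                f"(~{SMALL_PERTURBATION_CHI:.4g}); closed forms remain exact but the "
                "single-cycle 'small genetic perturbation' picture is strained",
                UserWarning,
                stacklevel=2,
            )

    def check_relaxation(self, tau_e: float) -> bool:
        """Warn unless delta_t / tau_e > 2.

        The between-cycle equilibrium assumption needs the inter-cycle
        interval to exceed about two exit lifetimes.  Returns True when
        the condition holds.
        """
        if tau_e <= 0:
            raise ValueError("tau_e must be positive")
        ok = self.delta_t / tau_e > 2.0
        if not ok:
            warnings.warn(
                f"delta_t / tau_e = {self.delta_t / tau_e:.3g} <= 2: genotype "
                "distribution may not re-equilibrate between cycles",
                UserWarning,
                stacklevel=2,
            )
        return ok

    def cycles_for(self, p_sf: float) -> float:
        """Real-valued cycle count to reach immigrant-homozygote prob p_sf."""
        return cycles_to_target(p_sf, self.chi)

    def time_for(self, p_sf: float) -> float:
        """Total time (years) to reach immigrant-homozygote prob p_sf."""
        return total_time(p_sf, self.chi, self.delta_t)


def apply_cycle(prev_eq: GenotypeDistribution, chi: float) -> GenotypeDistribution:
    """One immigration perturbation applied to the previous equilibrium.

    A fraction ``chi`` of the stationary population is replaced by
    immigrant homozygotes: P_S gains ``chi (1 - P_S)`` while P_N and
    P_NS are scaled by ``1 - chi``.  Returns the post-replacement
    *initial* distribution of the new relaxation epoch.
    """
    if not 0 <= chi < 1:
        raise ValueError("chi must lie in [0, 1)")
    return GenotypeDistribution(
        p_n=prev_eq.p_n * (1.0 - chi),
        p_s=prev_eq.p_s + chi - prev_eq.p_s * chi,
        p_ns=prev_eq.p_ns * (1.0 - chi),
    )


def delta_p_after_cycles(j: int, chi: float, delta_p00: float = 1.0) -> float:
    """Conserved difference after j cycles: (1-chi)^j (1+dP00) - 1."""
    if j < 0 or j != int(j):
        raise ValueError("j must be a non-negative integer")
    if not 0 <= chi < 1:
        raise ValueError("chi must lie in [0, 1)")
    if abs(delta_p00) > 1:
        raise ValueError("|delta_p00| must not exceed 1")
    return (1.0 - chi) ** int(j) * (1.0 + delta_p00) - 1.0


def subgroup_probs_after_cycles(j: int, chi: float) -> GenotypeDistribution:
    """Equilibrium genotype distribution after j cycles (pure-resident start).

    Closed forms P_N = (1-chi)^(2j), P_S = ((1-chi)^j - 1)^2 and
    P_NS = (1 - (2(1-chi)^j - 1)^2)/2, equivalent to composing
    :func:`apply_cycle` with the relaxation equilibrium j times.
    """
    if j < 0 or j != int(j):
        raise ValueError("j must be a non-negative integer")
    if not 0 <= chi < 1:
        raise ValueError("chi must lie in [0, 1)")
    r = (1.0 - chi) ** int(j)
    return GenotypeDistribution(
        p_n=r**2,
        p_s=(r - 1.0) ** 2,
        p_ns=(1.0 - (2.0 * r - 1.0) ** 2) / 2.0,
    )


def allele_frequencies(j: int, chi: float) -> tuple[float, float]:
    """Allele frequencies after j cycles: (p_immigrant, q_resident).

    p_j = 1 - (1 - chi)^j and q_j = (1 - chi)^j, the continent-island
    recursion with per-cycle migration fraction chi.
    """
    if j < 0 or j != int(j):
        raise ValueError("j must be a non-negative integer")
    if not 0 <= chi < 1:
        raise ValueError("chi must lie in [0, 1)")
    q = (1.0 - chi) ** int(j)
    return (1.0 - q, q)


def cycles_to_target(p_sf: float, chi: float) -> float:
    """Real-valued number of cycles J_f to reach immigrant-homozygote p_sf.

    J_f = ln(1 - sqrt(p_sf)) / ln(1 - chi); strictly decreasing in chi.
    The value is continuous (not rounded); see
    :func:`whole_cycles_to_target` for schedule construction.
    """
    if not 0 < p_sf < 1:
        raise ValueError("p_sf must lie strictly between 0 and 1")
    if not 0 < chi < 1:
        raise ValueError("chi must lie in (0, 1)")
    return math.log(1.0 - math.sqrt(p_sf)) / math.log(1.0 - chi)


def whole_cycles_to_target(p_sf: float, chi: float) -> int:
    """Smallest integer cycle count reaching at least p_sf."""
    return int(math.ceil(cycles_to_target(p_sf, chi) - 1e-12))


def total_time(p_sf: float, chi: float, delta_t: float) -> float:
    """Total dilution time T_f = J_f(chi) * delta_t, in years."""
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    return cycles_to_target(p_sf, chi) * delta_t


def chi_for_time(p_sf: float, delta_t: float, t_f: float) -> float:
    """Per-cycle fraction chi achieving dilution p_sf in total time t_f.

    Closed-form inversion of T_f = J_f(chi) * delta_t:

        chi = 1 - (1 - sqrt(p_sf))**(delta_t / t_f).
    """
    if not 0 < p_sf < 1:
        raise ValueError("p_sf must lie strictly between 0 and 1")
    if delta_t <= 0 or t_f <= 0:
        raise ValueError("delta_t and t_f must be positive")
    return 1.0 - (1.0 - math.sqrt(p_sf)) ** (delta_t / t_f)


def iterate_cycles(
    n_cycles: int, chi: float, delta_p00: float = 1.0
) -> list[GenotypeDistribution]:
    """Explicit perturbation/relaxation iteration, one entry per cycle.

    Starts from the equilibrium of ``delta_p00`` (entry 0) and applies
    ``apply_cycle`` followed by relaxation to equilibrium, n_cycles
    times.  Mainly an independent check of the closed forms.
    """
    dist = equilibrium_distribution(delta_p00)
    out = [dist]
    for _ in range(n_cycles):
        perturbed = apply_cycle(dist, chi)
        dist = equilibrium_distribution(perturbed.delta_p)
        out.append(dist)
    return out
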