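"""Genotype-subgroup dynamics at one neutral autosomal locus.

Within a stationary expected population (``N = N_eq``) each individual
is, for a chosen biallelic marker, a resident (Neanderthal) homozygote,
an immigrant (H. sapiens) homozygote, or a heterozygote, with ensemble
probabilities ``P_N + P_S + P_NS = 1``.  Random Mendelian mating at the
common reproduction rate and a common exit rate ``k_E`` give the coupled
system

    dP_N/dt = dP_S/dt = k_E [ (1 - (P_N + P_S))**2 / 4 - P_N P_S ],
    dP_NS/dt = -(dP_N/dt + dP_S/dt).

Two structural facts make the system solvable in closed form:

* ``delta_P0 = P_N - P_S`` is a dynamical invariant;
* ``Z = P_N + P_S`` relaxes exponentially at rate ``k_E`` toward
  ``(delta_P0**2 + 1) / 2``.

The t -> infinity limit is the Hardy-Weinberg-form equilibrium

    P_N(inf) = (delta_P0 + 1)**2 / 4,
    P_S(inf) = (delta_P0 - 1)**2 / 4,
    P_NS(inf) = (1 - delta_P0**2) / 2,

fully determined by the conserved difference, and satisfying
``P_NS(inf)**2 = 4 P_N(inf) P_S(inf)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "GenotypeDistribution",
    "GenotypeTrajectoryState",
    "genotype_trajectory",
    "equilibrium_distribution",
    "genotype_ode_oracle",
]

# input distributions whose components sum to 1 within this tolerance are
# renormalized silently; larger defects raise
_SUM_TOL = 1e-9


@dataclass(frozen=True)
class GenotypeDistribution:
    """Probabilities of the three genotype subgroups at one locus.

    Fields are the resident-homozygote, immigrant-homozygote and
    heterozygote probabilities (``p_n``, ``p_s``, ``p_ns``).  They must
    be non-negative and sum to 1 (defects below 1e-9 are renormalized).
    """

    p_n: float
    p_s: float
    p_ns: float

    def __post_init__(self) -> None:
        vals = (self.p_n, self.p_s, self.p_ns)
        if any(v < -1e-15 or v > 1 + 1e-12 for v in vals):
            raise ValueError(f"probabilities must lie in [0, 1]: {vals}")
        total = sum(vals)
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"genotype probabilities sum to {total!r}, not 1")
        if total != 1.0:
            object.__setattr__(self, "p_n", self.p_n / total)
            object.__setattr__(self, "p_s", self.p_s / total)
            object.__setattr__(self, "p_ns", self.p_ns / total)

    @property
    def delta_p(self) -> float:
        """Conserved difference P_N - P_S."""
        return self.p_n - self.p_s

    @property
    def z(self) -> float:
        """Total homozygote probability Z = P_N + P_S."""
        return self.p_n + self.p_s

    @property
    def allele_freq_immigrant(self) -> float:
        """Immigrant (H. sapiens) allele frequency p = P_S + P_NS / 2."""
        return self.p_s + 0.5 * self.p_ns

    @property
    def allele_freq_resident(self) -> float:
        """Resident (Neanderthal) allele frequency q = P_N + P_NS / 2."""
        return self.p_n + 0.5 * self.p_ns

    def as_array(self) -> np.ndarray:
        """Components in (P_N, P_S, P_NS) order."""
        return np.array([self.p_n, self.p_s, self.p_ns])

    def counts(self, n_eq: int) -> tuple[float, float, float]:
        """Expected subgroup counts (N_N, N_S, N_NS) in a tribe of n_eq."""
        return (self.p_n * n_eq, self.p_s * n_eq, self.p_ns * n_eq)


@dataclass(frozen=True)
class GenotypeTrajectoryState:
    """Reduced coordinates of one relaxation epoch: Z and delta_P0."""

    z: float
    delta_p0: float

    def __post_init__(self) -> None:
        if abs(self.delta_p0) > 1 + 1e-12:
            raise ValueError("|delta_p0| must not exceed 1")
        if not (abs(self.delta_p0) - 1e-12 <= self.z <= 1 + 1e-12):
            raise ValueError("Z must lie in [|delta_p0|, 1]")

    @property
    def z_equilibrium(self) -> float:
        """Fixed point of Z: (delta_P0**2 + 1) / 2."""
        return (self.delta_p0**2 + 1.0) / 2.0


def equilibrium_distribution(delta_p0: float) -> GenotypeDistribution:
    """Long-time genotype distribution implied by the conserved difference.

    Returns ((dP+1)^2/4, (dP-1)^2/4, (1-dP^2)/2) for dP = delta_p0 in
    [-1, 1]; the components sum to 1 identically.
    """
    if abs(delta_p0) > 1:
        raise ValueError("|delta_p0| must not exceed 1")
    return GenotypeDistribution(
        p_n=(delta_p0 + 1.0) ** 2 / 4.0,
        p_s=(delta_p0 - 1.0) ** 2 / 4.0,
        p_ns=(1.0 - delta_p0**2) / 2.0,
    )


def genotype_trajectory(
    init: GenotypeDistribution, k_e: float, t_grid: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Closed-form relaxation of the genotype probabilities.

    Returns an array of shape (len(t_grid), 3) with columns
    (P_N, P_S, P_NS).  The trajectory reproduces ``init`` exactly at
    t = 0, conserves P_N - P_S, and relaxes exponentially at rate k_e
    toward :func:`equilibrium_distribution` of the conserved difference.
    """
    if k_e <= 0:
        raise ValueError("k_e must be positive (no relaxation defined for k_e = 0)")
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")

    dp0 = init.delta_p
    z_inf = (dp0**2 + 1.0) / 2.0
    amp = init.z - z_inf
    decay = np.exp(-k_e * t)
    z = amp * decay + z_inf

    out = np.empty((t.size, 3))
    out[:, 0] = (z + dp0) / 2.0
    out[:, 1] = (z - dp0) / 2.0
    out[:, 2] = 1.0 - z
    return out


def genotype_ode_oracle(
    init: GenotypeDistribution, k_e: float, t_grid: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Numeric integration of the coupled genotype rate equations.

    Independent cross-check for :func:`genotype_trajectory`; integrates
    the full three-component system (not the reduced Z equation) with a
    high-order adaptive scheme.  Same return shape and column order.
    """
    if k_e <= 0:
        raise ValueError("k_e must be positive")
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        p_n, p_s, _p_ns = y
        common = k_e * (0.25 * (1.0 - (p_n + p_s)) ** 2 - p_n * p_s)
        return [common, common, -2.0 * common]

    order = np.argsort(t)
    t_sorted = t[order]
    y0 = [init.p_n, init.p_s, init.p_ns]
    if t_sorted[-1] == 0.0:
        return np.tile(np.array(y0), (t.size, 1))
    sol = solve_ivp(
        rhs,
        (0.0, float(t_sorted[-1])),
        y0,
        t_eval=t_sorted,
        rtol=1e-11,
        atol=1e-13,
        method="DOP853",
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    out = np.empty((t.size, 3))
    out[order] = sol.y.T
    return out
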