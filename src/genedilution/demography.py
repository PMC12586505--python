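"""Mean-field demography of a reference tribe.

The model tracks the *expected* reproductive population ``N`` of a
hunter-gatherer tribe, i.e. the mean over an idealized ensemble of
equivalent tribes.  With a mass-action birth term (proportional to the
number of possible female-male pairs, ``N/2 * N/2``), a per-capita exit
rate ``k_E`` (death, ageing out of reproduction, infertility) and a
migration term relaxing ``N`` toward its equilibrium, the dynamics are

    dN/dt = (k/4) N**2 - k_E N - gamma (N - N_eq),

with ``N_eq = 4 k_E / k`` the stable equilibrium.  In dimensionless
variables ``f = N / N_eq``, ``s = k_E t`` and ``n = gamma / k_E`` this
collapses to the quadratic flow

    df/ds = (f - 1)(f - n),

whose roots are the stable equilibrium ``f = 1`` and, for ``n > 1``, the
unstable equilibrium ``f = n`` (``N' = 4 gamma / k``).  Trajectories with
``0 <= f0 < n`` converge to 1; trajectories started above the unstable
root blow up in finite dimensionless time.

This module provides the closed-form trajectory, the finite blow-up
time, an independent numeric integrator used as a cross-check, and a
calibration helper converting birth-interval demography into the exit
mean lifetime ``tau_E = 1 / k_E``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "DemographicParams",
    "TrajectoryPoint",
    "DivergenceError",
    "equilibrium_population",
    "unstable_population",
    "population_trajectory",
    "divergence_time",
    "trajectory_oracle",
    "calibrate_tau_E",
]


class DivergenceError(ValueError):
    """Raised when a trajectory is requested at or beyond its blow-up time.

    Attributes
    ----------
    critical_s : float
        The dimensionless time at which the trajectory diverges; callers
        may plot up to (but not including) this asymptote.
    """

    def __init__(self, critical_s: float, message: str | None = None):
        self.critical_s = float(critical_s)
        super().__init__(
            message
            or f"trajectory diverges at dimensionless time s = {critical_s:.6g}"
        )


class TrajectoryPoint(NamedTuple):
    """One sample of the dimensionless population trajectory."""

    s: float  # dimensionless time k_E * t
    f: float  # dimensionless population N / N_eq


@dataclass(frozen=True)
class DemographicParams:
    """Rate constants of the tribe demography and derived quantities.

    Parameters
    ----------
    k : float
        Reproductive rate constant (per pair per year).
    k_e : float
        Exit rate constant (per individual per year).
    gamma : float
        Migration rate constant (per year).  The stable-equilibrium
        regime requires ``gamma > k_e`` (``n_ratio > 1``).
    """

    k: float
    k_e: float
    gamma: float

    def __post_init__(self) -> None:
        if self.k < 0 or self.k_e < 0 or self.gamma < 0:
            raise ValueError("rate constants must be non-negative")

    @property
    def n_eq(self) -> float:
        """Stable-equilibrium expected reproductive population, 4 k_E / k."""
        return equilibrium_population(self.k, self.k_e)

    @property
    def n_unstable(self) -> float:
        """Unstable-equilibrium expected population N' = 4 gamma / k."""
        return unstable_population(self.k, self.gamma)

    @property
    def n_ratio(self) -> float:
        """Dimensionless migration/exit ratio n = gamma / k_E."""
        if self.k_e == 0:
            raise ValueError("n_ratio undefined for k_e = 0")
        return self.gamma / self.k_e

    @property
    def tau_e(self) -> float:
        """Exit mean lifetime 1 / k_E in years."""
        if self.k_e == 0:
            raise ValueError("tau_e undefined for k_e = 0")
        return 1.0 / self.k_e

    @property
    def stable_regime(self) -> bool:
        """True when N_eq is the stable equilibrium (n_ratio > 1)."""
        return self.n_ratio > 1.0


def equilibrium_population(k: float, k_e: float) -> float:
    """Stable-equilibrium expected population ``N_eq = 4 k_E / k``.

    Parameters are the pair-reproduction rate constant ``k`` (> 0) and
    the exit rate constant ``k_e`` (>= 0).
    """
    if k <= 0:
        raise ValueError("k must be positive: no finite equilibrium for k = 0")
    if k_e < 0:
        raise ValueError("k_e must be non-negative")
    return 4.0 * k_e / k


def unstable_population(k: float, gamma: float) -> float:
    """Unstable-equilibrium expected population ``N' = 4 gamma / k``."""
    if k <= 0:
        raise ValueError("k must be positive")
    return 4.0 * gamma / k


def divergence_time(f0: float, n_ratio: float) -> float:
    """Finite blow-up time of the dimensionless trajectory, for f0 > n > 1.

    A trajectory started above the unstable root ``f = n`` diverges at

        s* = ln((f0 - 1) / (f0 - n)) / (n - 1),

    which is strictly positive.  Initial conditions ``0 <= f0 <= n``
    converge to the stable root instead and raise ``ValueError``.
    """
    if n_ratio <= 1:
        raise ValueError("divergence_time requires n_ratio > 1")
    if f0 <= n_ratio:
        raise ValueError(
            "trajectory converges for 0 <= f0 <= n_ratio; no finite divergence"
        )
    return math.log((f0 - 1.0) / (f0 - n_ratio)) / (n_ratio - 1.0)


def _critical_s(f0: float, n_ratio: float) -> float | None:
    """Blow-up time for any (f0, n_ratio), or None if the flow converges."""
    if f0 <= max(1.0, n_ratio):
        return None
    if abs(n_ratio - 1.0) < 1e-12:
        return 1.0 / (f0 - 1.0)
    # valid whenever f0 lies above both roots, for either root ordering
    return math.log((f0 - 1.0) / (f0 - n_ratio)) / (n_ratio - 1.0)


def population_trajectory(
    f0: float, n_ratio: float, s_grid: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Closed-form dimensionless trajectory f(s) of df/ds = (f-1)(f-n).

    For ``n != 1``,

        f(s) = [n (f0-1) - (f0-n) e^{(n-1)s}] / [(f0-1) - (f0-n) e^{(n-1)s}];

    for ``n = 1`` the confluent limit f(s) = 1 + (f0-1)/(1 - (f0-1)s)
    (solution of df/ds = (f-1)^2) is used.  ``f(0) = f0`` exactly.

    Raises
    ------
    DivergenceError
        If any requested ``s`` lies at or beyond the finite blow-up time
        of a trajectory started above the unstable root.
    """
    if n_ratio < 0:
        raise ValueError("n_ratio must be non-negative")
    if f0 < 0:
        raise ValueError("f0 must be non-negative")
    s = np.asarray(s_grid, dtype=float)
    if np.any(s < 0):
        raise ValueError("dimensionless times must be non-negative")

    s_crit = _critical_s(f0, n_ratio)
    if s_crit is not None and np.any(s >= s_crit):
        raise DivergenceError(s_crit)

    if abs(n_ratio - 1.0) < 1e-12:
        return 1.0 + (f0 - 1.0) / (1.0 - (f0 - 1.0) * s)

    n = n_ratio
    if n > 1:
        # divide through by e^{(n-1)s} so the exponential decays
        e = np.exp(-(n - 1.0) * s)
        num = n * (f0 - 1.0) * e - (f0 - n)
        den = (f0 - 1.0) * e - (f0 - n)
    else:
        e = np.exp((n - 1.0) * s)
        num = n * (f0 - 1.0) - (f0 - n) * e
        den = (f0 - 1.0) - (f0 - n) * e
    return num / den


def trajectory_points(
    f0: float, n_ratio: float, s_grid: Sequence[float] | np.ndarray
) -> list[TrajectoryPoint]:
    """`population_trajectory` packaged as (s, f) pairs."""
    f = population_trajectory(f0, n_ratio, s_grid)
    return [TrajectoryPoint(float(si), float(fi)) for si, fi in zip(np.asarray(s_grid, float), f)]


def trajectory_oracle(
    f0: float, n_ratio: float, s_grid: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Adaptive numeric integration of df/ds = (f-1)(f-n).

    Independent cross-check for :func:`population_trajectory`; the two
    agree to ~1e-8 absolute on the convergent regime.
    """
    s = np.asarray(s_grid, dtype=float)
    if np.any(s < 0):
        raise ValueError("dimensionless times must be non-negative")
    s_crit = _critical_s(f0, n_ratio)
    if s_crit is not None and np.any(s >= s_crit):
        raise DivergenceError(s_crit)

    order = np.argsort(s)
    s_sorted = s[order]
    t_span = (0.0, float(s_sorted[-1]) if len(s_sorted) else 0.0)
    if t_span[1] == 0.0:
        return np.full_like(s, float(f0))
    sol = solve_ivp(
        lambda _s, f: (f - 1.0) * (f - n_ratio),
        t_span,
        [float(f0)],
        t_eval=s_sorted,
        rtol=1e-12,
        atol=1e-14,
        method="DOP853",
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    out = np.empty_like(s)
    out[order] = sol.y[0]
    return out


def calibrate_tau_E(mean_birth_interval: float, survival_to_reproduction: float) -> float:
    """Exit mean lifetime implied by stationary recruitment bookkeeping.

    At demographic stationarity the per-reproductive-individual
    recruitment rate equals the exit rate ``k_E``: each couple produces
    one surviving recruit every ``interval / survival`` years, shared
    over the two parents, so

        tau_E = 2 * mean_birth_interval / survival_to_reproduction.

    With a 6-year mean inter-birth interval per woman and survival 0.5
    to reproductive age this gives the ~24-year exit lifetime typical of
    extant hunter-gatherer demography.
    """
    if mean_birth_interval <= 0:
        raise ValueError("mean_birth_interval must be positive")
    if not 0 < survival_to_reproduction <= 1:
        raise ValueError("survival_to_reproduction must lie in (0, 1]")
    return 2.0 * mean_birth_interval / survival_to_reproduction
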