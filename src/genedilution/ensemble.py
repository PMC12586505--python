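"""Finite-tribe and finite-ensemble statistical noise.

The analytics of the dilution model describe an ensemble mean; a real
tribe of ``N_eq`` reproductive individuals is a finite sample of that
ensemble, and its genotype counts fluctuate around the expectation.
Those fluctuations are the model's proxy for genetic drift:

* the immigrant-homozygote count in one tribe is Binomial(N_eq, P_Sf);
* the joint genotype counts are Multinomial(N_eq, (P_S, P_N, P_NS));
* the ensemble estimate of P_Sf from M tribes has standard deviation
  sqrt(P_Sf (1 - P_Sf) / (N_eq M)), with a Gaussian 2-sigma 95% CI
  (the model's convention is exactly 2 sigma, not 1.96);
* across n independent loci with common final probability P_Sf, the
  per-individual probability of carrying at least one resident allele
  is 1 - P_Sf**n, and the carrier count in a tribe is again binomial.

Everything here is closed-form; the distributions themselves are
delegated to scipy.stats (log-space evaluation keeps the multinomial
exact for tribe sizes up to ~1e4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import stats

from .genotypes import GenotypeDistribution

__all__ = [
    "TribeEnsemble",
    "MultiLocusSpec",
    "CarrierStats",
    "tribe_homozygote_pmf",
    "tribe_fraction_sd",
    "ensemble_estimate_ci",
    "tribe_genotype_pmf",
    "multilocus_homozygosity_stats",
    "carrier_stats",
    "carrier_sd_maximizer",
]


@dataclass(frozen=True)
class TribeEnsemble:
    """Per-tribe genotype counts for M finite tribes of N_eq individuals.

    ``counts`` has shape (M, 3) with columns (k_S, k_N, k_NS); each row
    sums to N_eq.
    """

    n_eq: int
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[1] != 3:
            raise ValueError("counts must have shape (M, 3)")
        if counts.shape[0] < 1:
            raise ValueError("at least one tribe is required")
        if np.any(counts < 0):
            raise ValueError("genotype counts must be non-negative")
        if np.any(counts.sum(axis=1) != self.n_eq):
            raise ValueError("each tribe's genotype counts must sum to n_eq")
        object.__setattr__(self, "counts", counts)

    @property
    def m(self) -> int:
        """Number of tribes in the ensemble."""
        return self.counts.shape[0]

    @property
    def k_s(self) -> np.ndarray:
        """Immigrant-homozygote count per tribe."""
        return self.counts[:, 0]

    @property
    def k_n(self) -> np.ndarray:
        """Resident-homozygote count per tribe."""
        return self.counts[:, 1]

    @property
    def k_ns(self) -> np.ndarray:
        """Heterozygote count per tribe."""
        return self.counts[:, 2]

    def estimate_p_sf(self) -> float:
        """Ensemble estimate of the immigrant-homozygote probability."""
        return float(self.k_s.mean()) / self.n_eq

    def mean_distribution(self) -> GenotypeDistribution:
        """Ensemble-mean genotype distribution."""
        mean = self.counts.mean(axis=0) / self.n_eq
        return GenotypeDistribution(p_n=mean[1], p_s=mean[0], p_ns=mean[2])


@dataclass(frozen=True)
class MultiLocusSpec:
    """A panel of statistically independent loci with a common final P_Sf."""

    n_loci: int
    p_sf: float

    def __post_init__(self) -> None:
        if self.n_loci < 1 or self.n_loci != int(self.n_loci):
            raise ValueError("n_loci must be a positive integer")
        if not 0 <= self.p_sf <= 1:
            raise ValueError("p_sf must lie in [0, 1]")

    @property
    def carrier_prob(self) -> float:
        """Per-individual probability of >= 1 resident allele: 1 - P_Sf^n."""
        return 1.0 - self.p_sf**self.n_loci


def tribe_homozygote_pmf(n_eq: int, p_sf: float) -> np.ndarray:
    """Binomial pmf of the immigrant-homozygote count in one tribe.

    Returns the probabilities of k_S = 0..N_eq; mean N_eq * P_Sf and
    variance N_eq * P_Sf (1 - P_Sf).
    """
    if n_eq < 1:
        raise ValueError("n_eq must be at least 1")
    if not 0 <= p_sf <= 1:
        raise ValueError("p_sf must lie in [0, 1]")
    return stats.binom.pmf(np.arange(n_eq + 1), n_eq, p_sf)


def tribe_fraction_sd(n_eq: int, p_sf: float) -> float:
    """Standard deviation of the fraction k_S / N_eq in a single tribe.

    sqrt(P_Sf (1 - P_Sf)) / sqrt(N_eq): the drift-like noise on one
    tribe, vanishing as N_eq grows or P_Sf approaches 0 or 1.
    """
    if n_eq < 1:
        raise ValueError("n_eq must be at least 1")
    if not 0 <= p_sf <= 1:
        raise ValueError("p_sf must lie in [0, 1]")
    return math.sqrt(p_sf * (1.0 - p_sf)) / math.sqrt(n_eq)


def ensemble_estimate_ci(p_sf: float, n_eq: int, m: int) -> tuple[float, float]:
    """Gaussian 2-sigma band for the M-tribe estimate of P_Sf.

    The ensemble average of k_S / N_eq over M tribes has standard
    deviation sqrt(P_Sf (1 - P_Sf) / (N_eq M)); the returned interval is
    P_Sf -/+ 2 sigma (the model's 95% convention uses exactly 2, not
    1.96), clipped to [0, 1].
    """
    if n_eq < 1 or m < 1:
        raise ValueError("n_eq and m must be at least 1")
    if not 0 <= p_sf <= 1:
        raise ValueError("p_sf must lie in [0, 1]")
    sigma = math.sqrt(p_sf * (1.0 - p_sf) / (n_eq * m))
    return (max(0.0, p_sf - 2.0 * sigma), min(1.0, p_sf + 2.0 * sigma))


def tribe_genotype_pmf(
    n_eq: int, dist: GenotypeDistribution, counts: np.ndarray | None = None
) -> np.ndarray:
    """Multinomial pmf of the joint genotype counts (k_S, k_N, k_NS).

    With ``counts`` of shape (..., 3) the pmf is evaluated at those
    compositions of N_eq (log-space via scipy, exact to ~1e-13 relative
    even for N_eq ~ 1e4).  With ``counts=None`` all compositions are
    enumerated and an array of shape (n_comp, 4) is returned whose
    columns are (k_S, k_N, k_NS, probability); only sensible for small
    N_eq.  The marginal over k_N, k_NS is the binomial of
    :func:`tribe_homozygote_pmf`.
    """
    if n_eq < 1:
        raise ValueError("n_eq must be at least 1")
    p = (dist.p_s, dist.p_n, dist.p_ns)
    rv = stats.multinomial(n_eq, p)
    if counts is not None:
        counts = np.asarray(counts)
        if counts.shape[-1] != 3:
            raise ValueError("counts must have a trailing dimension of 3")
        if np.any(counts.sum(axis=-1) != n_eq):
            raise ValueError("compositions must sum to n_eq")
        return rv.pmf(counts)
    ks, kn = np.meshgrid(np.arange(n_eq + 1), np.arange(n_eq + 1), indexing="ij")
    mask = ks + kn <= n_eq
    ks, kn = ks[mask], kn[mask]
    comp = np.stack([ks, kn, n_eq - ks - kn], axis=1)
    return np.column_stack([comp, rv.pmf(comp)])


def multilocus_homozygosity_stats(spec: MultiLocusSpec) -> tuple[float, float]:
    """Mean and variance of the number of immigrant-homozygous loci.

    Across n independent loci with common P_Sf the count n_S is
    binomial: mean n * P_Sf, variance n * P_Sf (1 - P_Sf).
    """
    mean = spec.n_loci * spec.p_sf
    var = spec.n_loci * spec.p_sf * (1.0 - spec.p_sf)
    return (mean, var)


class CarrierStats(NamedTuple):
    """Statistics of resident-allele carriers across a locus panel."""

    carrier_prob: float  # per-individual P(>= 1 resident allele) = 1 - P_Sf^n
    mean_frac: float  # expected carrier fraction <k>/N_eq (equals carrier_prob)
    sd_frac: float  # sd of the carrier fraction in one tribe
    ensemble_sd: float  # sd of the ensemble-mean carrier fraction over M tribes


def carrier_stats(spec: MultiLocusSpec, n_eq: int, m: int = 1) -> CarrierStats:
    """Carrier statistics for individuals with >= 1 resident allele.

    The carrier count k in a tribe is Binomial(N_eq, 1 - P_Sf^n), so

        <k>/N_eq  = 1 - P_Sf^n,
        sd(k/N_eq) = sqrt((1 - P_Sf^n) P_Sf^n / N_eq),

    and the ensemble mean over M tribes has sd(k/N_eq)/sqrt(M).
    """
    if n_eq < 1 or m < 1:
        raise ValueError("n_eq and m must be at least 1")
    surv = spec.p_sf**spec.n_loci  # probability of being immigrant-homozygous everywhere
    carrier = 1.0 - surv
    sd_frac = math.sqrt(carrier * surv / n_eq)
    return CarrierStats(
        carrier_prob=carrier,
        mean_frac=carrier,
        sd_frac=sd_frac,
        ensemble_sd=sd_frac / math.sqrt(m),
    )


def carrier_sd_maximizer(p_sf: float) -> float:
    """Panel size n at which the carrier-fraction sd peaks.

    sd(k/N_eq) is maximal where P_Sf^n = 1/2, i.e. at the real-valued
    n* = ln(1/2) / ln(P_Sf); integer panels floor(n*) and ceil(n*)
    bound every other integer n.
    """
    if not 0 < p_sf < 1:
        raise ValueError("p_sf must lie strictly between 0 and 1")
    return math.log(0.5) / math.log(p_sf)
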