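"""Genotype relaxation at one neutral locus within a stationary tribe.

Starts from an even split of resident and immigrant homozygotes (no
heterozygotes) and follows the three genotype probabilities to their
Hardy-Weinberg-form equilibrium, which depends only on the conserved
difference P_N - P_S.
"""

import numpy as np

from genedilution import GenotypeDistribution, equilibrium_distribution, genotype_trajectory

tau_e = 24.0  # exit mean lifetime, years
init = GenotypeDistribution(p_n=0.5, p_s=0.5, p_ns=0.0)

t = np.array([0.0, 0.5, 1.0, 2.0, 4.0]) * tau_e
traj = genotype_trajectory(init, 1.0 / tau_e, t)
print("   t/tau_E    P_N     P_S     P_NS")
for ti, (p_n, p_s, p_ns) in zip(t / tau_e, traj):
    print(f"    {ti:5.1f}   {p_n:.4f}  {p_s:.4f}  {p_ns:.4f}")

eq = equilibrium_distribution(init.delta_p)
print(f"equilibrium: ({eq.p_n:.4f}, {eq.p_s:.4f}, {eq.p_ns:.4f})")
print(f"heterozygote identity P_NS^2 - 4 P_N P_S = "
      f"{eq.p_ns**2 - 4 * eq.p_n * eq.p_s:.2e}")

# P_N - P_S never changes; the homozygote excess decays as e^{-t/tau_E},
# so by two exit lifetimes the distribution is ~87% of the way to its
# equilibrium -- the basis for spacing immigration cycles > 2 tau_E apart.
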