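"""Mean-field demography of a reference tribe.

Builds the dimensionless population trajectory f(s) = N(s)/N_eq for a
few initial sizes at the reference migration/exit ratio n = 3.3, and
shows the finite blow-up time for a start above the unstable root.
"""

import numpy as np

from genedilution import divergence_time, equilibrium_population, population_trajectory

# a tribe with exit lifetime 24 yr (k_E = 1/24 per yr) and pair
# reproduction rate tuned so ~100 reproductive individuals are stable
k_e = 1.0 / 24.0
k = 4.0 * k_e / 100.0
print(f"equilibrium reproductive population N_eq = {equilibrium_population(k, k_e):.0f}")

s = np.linspace(0.0, 5.0, 6)  # dimensionless time, units of tau_E
for f0 in (0.25, 0.5, 1.0, 2.0):
    f = population_trajectory(f0, 3.3, s)
    print(f"f0 = {f0:4.2f}: " + "  ".join(f"f({si:.0f})={fi:.4f}" for si, fi in zip(s, f)))

s_crit = divergence_time(4.0, 3.3)
print(f"a tribe started at f0 = 4 (above the unstable root n = 3.3) "
      f"blows up at s = {s_crit:.4f}, i.e. after {24 * s_crit:.0f} years")

# Every trajectory started below n converges to f = 1 (N = N_eq) within a
# few exit lifetimes: the population is effectively stationary, which is
# the regime all the genetic results condition on.
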