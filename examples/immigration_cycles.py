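"""Recurrent immigration cycles diluting a pure-resident population.

Applies the closed-form cycle recursion at the reference per-cycle
fraction chi = 2/30 and prints the equilibrium genotype probabilities
and allele frequencies after each block of cycles, together with the
continent-island equivalence check.
"""

from genedilution import allele_frequencies, subgroup_probs_after_cycles

chi = 2.0 / 30.0
print(f"per-cycle immigrant fraction chi = {chi:.4f}")
print("   j     P_N     P_S     P_NS    p(immigrant)  q(resident)")
for j in (0, 1, 5, 10, 20, 40, 80):
    d = subgroup_probs_after_cycles(j, chi)
    p, q = allele_frequencies(j, chi)
    print(f"  {j:3d}  {d.p_n:.4f}  {d.p_s:.4f}  {d.p_ns:.4f}     {p:.4f}       {q:.4f}")
    # allele frequencies from the genotype closed forms equal the
    # classical continent-island recursion q_j = (1 - chi)^j
    assert abs(q - d.allele_freq_resident) < 1e-12

# Resident homozygotes decay as (1-chi)^(2j); heterozygotes rise and then
# fall as the immigrant allele takes over -- after ~80 cycles the
# resident allele survives mostly in heterozygotes and trace homozygotes.
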