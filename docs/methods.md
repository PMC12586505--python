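# Methods

## Model and assumptions

The package implements a mean-field, neutral model of genetic
replacement. Its core idealizations:

* **Ensemble picture.** The resident metapopulation is an (ideally
  infinite) set of equivalent reference tribes. Analytic quantities are
  ensemble means ("expected population"); single tribes fluctuate
  around them.
* **Demographic stationarity.** The expected reproductive population
  obeys `dN/dt = (k/4)N² − k_E N − γ(N − N_eq)` with `N_eq = 4k_E/k`.
  In the regime `n = γ/k_E > 1`, all initial conditions `0 ≤ f0 < n`
  converge to `N_eq` within a few exit lifetimes, so the genetic
  dynamics are derived at fixed `N = N_eq`. Rate constants are the
  zeroth-order terms of an expansion around equilibrium; no age
  structure, explicit sexes (exact female–male parity is assumed), or
  density-dependent refinements.
* **Neutrality.** All three genotype subgroups share the same
  reproduction and exit rates: the marker is autosomal and fitness-free
  by construction. There is no option to add selection.
* **Equilibration between cycles.** The cycle recursion composes each
  instantaneous perturbation with the *equilibrium* of the relaxation
  that follows; this is accurate when `Δt/τ_E > 2` (relaxation is
  exponential with lifetime `τ_E = 1/k_E`). `CycleSchedule` warns, but
  does not refuse, outside that regime, since the closed forms remain
  evaluable and useful for exploration.
* **One-way flow.** The source population is unbounded and fixed
  (pure immigrant homozygotes); back-migration is not modelled.
* **Independent loci.** Multi-locus statistics assume statistical
  independence across loci (no linkage).

## Parameters

| symbol | meaning | units | reference value |
|---|---|---|---|
| `k` | pair reproduction rate constant | /pair/yr | `4 k_E / N_eq` |
| `k_E` | exit rate (death, ageing out, infertility) | /yr | `1/24` |
| `τ_E` | exit mean lifetime `1/k_E` | yr | 24 |
| `γ`, `n` | migration rate; `n = γ/k_E` | /yr, — | `n = 3.3` |
| `N_eq` | stationary reproductive tribe population | individuals | 100 (50 in the dispersion study) |
| `χ` | immigrant fraction per cycle | — | `2/30 ≈ 0.067`; realistic window 0.008–0.08 |
| `Δt` | inter-cycle interval | yr | 50–150 |
| `P_S,f` | target immigrant-homozygote probability | — | 0.990 |
| `M` | tribes in a finite ensemble | — | 10–500 |
| `n_loci` | independent loci in a carrier panel | — | 10 |

The exit lifetime is calibrated from hunter-gatherer demography: at
stationarity the per-reproductive-individual recruitment rate equals
`k_E`; one surviving recruit per couple every `interval/survival` years,
shared over two parents, gives `τ_E = 2·interval/survival`. With the
observed 4–8-year inter-birth interval (midpoint 6) and ~0.5 survival to
reproductive age, `τ_E ≈ 24` yr. Other bookkeeping conventions (e.g.
per-woman rates) would rescale this; the per-couple convention is used
because it is the one consistent with the pair-reproduction term of the
demographic equation.

## The stochastic simulator

`simulate.simulate_ensemble` evolves `M` tribes of exactly `N_eq`
individuals (Moran-style fixed size: the analytics condition on the
stationary population, so demographic noise is deliberately excluded).
Genotypes are coded 0/1/2 by immigrant-allele count. Per step of
`Δt_step ≤ τ_E/20` years:

1. each individual exits with probability `Δt_step/τ_E` and is replaced
   by the Mendelian offspring of a uniformly random ordered pair of
   distinct survivors (the geometric exit process approximates the
   exponential to < 3 % at this step size);
2. tribe–environment exchange is applied (see below);
3. every `Δt` years, a cycle replaces `Binomial(N_eq, χ)` random
   individuals per tribe with immigrant homozygotes. The binomial law
   makes the *ensemble-average* replaced fraction exactly `χ` — the
   quantity the closed forms are written in — even when `χ·N_eq` is not
   an integer; `immigrants="exact"` switches to `round(χ·N_eq)`, which
   is biased whenever the product is fractional (e.g. 7 vs 6.67 for
   `χ = 2/30`, `N_eq = 100`, compounding to a visible allele-frequency
   offset over 20 cycles).

**Exchange with the environment.** In the analytic model, tribes
exchange individuals with a demographic/genetic bath in a way that does
not alter the genotype distribution; the exchange term cancels
identically out of the genotype equations, so the model assigns it no
finite rate — its entire content is that each tribe stays a
representative sample of the ensemble. The simulator's default
(`bath_ratio = inf`) realizes exactly that: after each step individuals
are randomly permuted across tribes, conserving all genotype totals.
Two alternatives expose the physics the idealization hides:

* `bath_ratio = r` (finite): each individual is swapped at rate
  `r·k_E` for a draw from a pool whose composition matches the current
  ensemble genotype frequencies (largest-remainder rounding). The pool
  is balanced because naive per-draw sampling would make the ensemble
  mean itself random-walk at scale `√(t/(M·N_eq))` — an artifact of a
  finite ensemble standing in for an infinite bath. At `r ≈ 3` (the
  demographic migration/exit ratio) the residual kin correlation of
  tribe-mates born since their tribe's last exchange leaves a 15–30 %
  over-dispersion of tribe counts relative to the binomial law.
* `bath_ratio = 0`: isolated tribes. Within-tribe drift then
  accumulates freely; after ~80 turnover lifetimes the across-tribe
  variance of the immigrant-homozygote fraction is several-fold above
  binomial, with the corresponding Wahlund-style heterozygote deficit
  in the ensemble mean. This is classical drift, which the mean-field
  analytics deliberately do not describe.

**What the simulator does and does not emulate.** It realizes the
model's own idealizations — stationary tribe size, neutral Mendelian
mixing, representative-sample exchange, one-way immigration at
ensemble-average fraction `χ`. It does not emulate spatial structure,
band-level substructure within tribes, variable tribe sizes, age
structure, linkage, or selection. Agreement between simulator and
closed forms therefore validates the internal consistency of the
model, not the fidelity of those idealizations to real Pleistocene
populations.

**Monte-Carlo uncertainty.** Tribes coupled through a common bath are
not independent, and the ensemble mean of a single finite-`M` run
performs an undamped neutral random walk (driven by immigration and
reproduction noise, only weakly contracted by `(1−χ)` per cycle) whose
stationary scale, ≈ 0.011 on the allele frequency at `N_eq = 100`,
`M = 200`, is invariant *relative to* the naive across-tribe standard
error — both scale as `(M·N_eq)^{-1/2}`. Validation of ensemble means
therefore uses the standard error over independent replicate
simulations (8 replicates in the acceptance test), which is the
statistically correct Monte-Carlo SE for the ensemble-mean estimator.
Tribe-level dispersion is tested with a chi-square goodness of fit of
final immigrant-homozygote counts against `Binomial(N_eq, P̂_S,f)`
(bins pooled to expected counts ≥ 5; one degree of freedom charged for
the estimated mean), at `N_eq = 50`, `M = 500`.

## Numerical choices

* Closed-form trajectories use the decaying-exponential arrangement of
  the solution (divide through by `e^{(n−1)s}` when `n > 1`) so large
  `s` cannot overflow; the confluent case `n = 1` uses the analytic
  limit `f(s) = 1 + (f0−1)/(1 − (f0−1)s)` rather than failing.
* Trajectories started above the unstable root raise a typed
  `DivergenceError` carrying the finite blow-up time
  `s* = ln((f0−1)/(f0−n))/(n−1)`, so callers can plot up to the
  asymptote; `inf`/`NaN` are never returned.
* The independent ODE oracles integrate the *unreduced* systems with
  `DOP853` at `rtol = 1e-12`; closed form and oracle are required to
  agree to 1e-8 absolute, comfortably above integrator error even next
  to the unstable root.
* Genotype distributions must sum to 1 within 1e-9 (inputs with smaller
  defects are renormalized silently, larger ones rejected); returned
  trajectories conserve the total and the difference `P_N − P_S` to
  1e-12.
* Multinomial tribe-count probabilities are evaluated in log space
  (via scipy's gammaln-based multinomial), exact to ~1e-13 relative up
  to `N_eq ≈ 10⁴`.
* The ensemble confidence band uses exactly 2σ, not 1.96σ — the model's
  stated Gaussian convention for its 95 % interval. Statistics users
  expecting 1.96 should note the difference.
* `cycles_to_target` returns the real-valued cycle count (the dilution
  time is a continuous function of `χ`); `whole_cycles_to_target`
  applies the ceiling for schedule construction.
* t → ∞ genotype limits are provided by `equilibrium_distribution`
  rather than by passing large times.

## Design choices that were genuinely open

* **Replicate-based Monte-Carlo SE** (see above): the across-tribe SE
  underestimates the uncertainty of a coupled ensemble's mean at any
  ensemble size, so replication is the only honest error bar.
* **Well-mixed exchange as default**: the binomial/multinomial
  tribe-count laws are exactly the representative-sample idealization;
  making the idealization the default keeps "simulate then compare to
  the analytics" a like-for-like exercise, while finite-rate and
  isolated modes remain available to quantify departures.
* **Binomial immigrant numbers as default**: unbiased realization of
  the ensemble-average fraction `χ`; exact replacement kept as an
  option for sensitivity.
* **Figure-family presets** live in the CLI (`--fig1` … `--fig5`) with
  the curve parameters used for the reference figures; the initial-size
  set for the demographic family `{0, 0.5, 1, 2, 3.3, 3.5}` includes
  one divergent start to display the asymptote.

## Problem sizes

The test suite runs the Monte-Carlo validation at `N_eq = 100, M = 200,
20 cycles × 8 replicates` plus one `N_eq = 50, M = 500` dispersion run
(≈ 25 s total on one core); unit tests use smaller ensembles
(`N_eq = 30–50`, `M = 40–300`). The acceptance script itself is pure
closed-form evaluation and runs in under a second.

## Known limitations

* Mean-field only: no spatial structure, contact zones, migration
  barriers, or regionally varying admixture intensity.
* One-way gene flow; no feedback of resident alleles into the source.
* The drift proxy quantifies scatter *around* the ensemble mean under
  the representative-sample idealization; it is not a substitute for a
  drift-explicit (e.g. Wright–Fisher) treatment of isolated
  populations, as the `bath_ratio = 0` mode makes visible.
* The logistic-growth limit of the demographic equation (rate constants
  linear in `N`) is noted for orientation but not implemented.
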