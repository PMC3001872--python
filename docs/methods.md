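# Methods

## The model and its assumptions

The package simulates a network of intercellular influences among seven
species in an arbitrary well-mixed local volume of brain tissue: surviving
and dead neurons (N_s, N_d), quiescent and proliferating astroglia (A_q,
A_p), pro-inflammatory reactive (M1) and anti-inflammatory resting (M2)
microglia, and the number of amyloid-β molecules (Aβ).  The modelling
assumptions are:

* **Well-mixed volume.** Spatial transport (diffusion, chemotaxis) is
  neglected; signal dispersion is taken to be fast relative to the cell
  events it drives.
* **Constant risk of neuronal death.** Death events occur at a rate set by
  the current populations, independently of any individual neuron's state.
* **Conversion, not proliferation.** Each cell type switches between two
  states within a fixed pool, so the pair totals N_s+N_d, A_q+A_p and
  M1+M2 are conserved exactly.  Neuronal death is irreversible; the
  astroglial and microglial conversions are reversible.
* **Mass-action-like pathway terms.** Each of the 16 directed pathways
  (plus the Aβ removal path) contributes a term that is first order in its
  *source* species, with a rate α in 1/year.  The right-hand side is
  therefore linear in the state away from the floors described below, and
  positively homogeneous everywhere.

The first-order-in-source form is a deliberate reconstruction choice: it
is the simplest reading consistent with the pathway network's stated
structure (which species each equation involves, which pathways promote
and which inhibit, the antisymmetric sensitivity structure of the
conserved pairs), and it is kept behind a single replaceable function
(`adnet.model.rhs`) so an alternative algebraic reading can be swapped in
without touching the simulator, sensitivity, or scenario layers.  Two
consequences of the reconstruction are documented as known deviations at
the end of this note.

Two of the seventeen rates both describe resting-microglial opposition to
Aβ and are disambiguated by mechanism: α16 is M2-mediated clearance (term
α16·M2) while α_r is first-order removal (term α_r·Aβ).  With α_r =
1/year this gives Aβ a ≈1-year relaxation time, which is what makes the
amyloid level settle after roughly three years; an α_r·M2 form would
instead annihilate Aβ within days.

### Floors and non-negativity

* **Irreversible death floor.** The net neuron-conversion flux
  φ_N = α2·A_p + α3·M1 − α1·A_q is floored at zero, so the dead-neuron
  count never decreases.  At the default parameters the floor is inactive
  (φ_N = 10/yr > 0 at t = 0 and stays positive).
* **Zero-boundary projection.** Populations are counts and cannot go
  negative.  If a species sits at zero and its conversion flux would drain
  it further, the flux is zeroed, which freezes its conversion partner
  with it and preserves the pair total.  Sampled states are additionally
  projected onto the non-negative orthant; for a conversion pair the
  partner absorbs the (integrator-tolerance-sized) clipped amount.

## Parameters

Defaults, all in 1/year (rates) or counts per local volume (initial
values); every one is overridable through the YAML/JSON config or the
library API.

| Rate | Pathway | Default | | Rate | Pathway | Default |
|---|---|---|---|---|---|---|
| α1 | A_q → N_s | 1e-5 | | α10 | N_d → M1 | 1e-2 |
| α2 | A_p → N_d | 1e-3 | | α11 | N_s ⊥ M1 | 1e-2 |
| α3 | M1 → N_d | 1e-2 | | α12 | A_q ⊥ M1 | 1e-4 |
| α4 | M2 → A_q | 1e-4 | | α13 | Aβ → M1 | 1e-2 |
| α5 | M1 → A_p | 1e-2 | | α14 | M2 ⊥ M1 | 1e-4 |
| α6 | N_s → M2 | 1e-2 | | α15 | N_s → Aβ | 1 |
| α7 | A_q → M2 | 1e-4 | | α16 | M2 ⊥ Aβ | 1e-2 |
| α8 | Aβ ⊥ M2 | 1e-2 | | α_r | Aβ removal | 1 |
| α9 | M1 ⊥ M2 | 1e-2 | | | | |

Initial populations: N_s = 1e4, N_d = 1e2, A_q = 1e5, A_p = 1e3,
M1 = 1e3, M2 = 1e5, Aβ = 1e3.  Horizon: 20 years.

The rate pattern encodes the biology: neuron-to-amyloid production (α15)
is the fastest path (each surviving neuron sustains about one Aβ molecule
per year), while the restorative chain M2 → A_q → N_s (α4, α1) is the
slowest, reflecting the near-irreversibility of neuronal decline.

## Numerical choices

* **Integrator.** Adaptive explicit Runge–Kutta (scipy RK45), rtol 1e-8,
  atol 1e-6, dense output evaluated on the sample grid (default every
  0.1 year) so there are no restart artifacts at sample boundaries.  The
  maximum step is capped at 0.5 year so the solver resolves the
  non-smooth clamp boundaries; stiff multistep methods (LSODA/BDF) are
  avoided because the discontinuous projection makes their step-size
  control chatter at the M1 = 0 surface.
* **Conservation.** The three pair derivatives are exact negatives at
  every right-hand-side evaluation, so any Runge–Kutta method conserves
  the pair totals to floating-point roundoff; the observed 20-year drift
  is ~1e-16 relative, far inside the 1e-6 contract.
* **Cross-check.** A fixed-step classical RK4 integrator at dt = 1e-3
  year serves as an independent numerical oracle; the two agree to better
  than 1e-4 of each species' dynamic range on the baseline run (observed
  ~7e-7).
* **Sensitivity schemes.** Rates: central fractional differences,
  S = [X(T; α(1+f)) − X(T; α(1−f))]/(2fα) with f = 0.025 by default; the
  quotient is converged (halving f moves unclamped coefficients by
  <0.3%).  Initial values: forward quotient for a tenfold increase, with
  the 0.1× variant computed alongside and carried on the same record (the
  10× value is the headline).  Classification of a rate is by the largest
  |S| over the four monitored outputs (N_s, N_d, M1, M2): Strong ≥ 1e4,
  Moderate ≥ 1e3, else Weak; the thresholds are config knobs because the
  printed class labels are not a pure function of the printed
  coefficients.
* **Clamp flagging.** A finite difference across a non-negativity clamp is
  non-smooth and can be silently misleading (e.g. both perturbed runs
  pinned at M1 = 0 yield a zero quotient), so any record whose underlying
  runs touch a clamp or the death floor is flagged `clamped` rather than
  suppressed.  The baseline 20-year run reaches M1 = 0 near year 19, so
  full-horizon records carry the flag; a 5-year horizon does not.
* **Stabilization time.** Earliest sampled time after which a species
  stays within a relative band (default 5%) of its final sampled value;
  evaluated on sampled points only.  For a pure exponential with a 1-year
  time constant this gives −ln(0.05) ≈ 3 years, and the baseline Aβ
  trace settles at 2.8 years.
* **Degenerate inputs.** Zero rates are allowed (they switch pathways
  off; the all-zero model holds its initial state exactly), negative
  rates and initial values are validation errors, and a multiplicative
  perturbation of a zero initial value is rejected rather than silently
  returning zero.

## Design choices where the design was open

* The equation reconstruction itself (first order in source species) and
  the α16/α_r disambiguation, discussed above.
* Tenfold initial-value perturbations are reported as the 10× forward
  quotient with the 0.1× variant alongside, since the two factors are
  stated without a combination rule.
* The 5% stabilization band and the Strong/Moderate/Weak thresholds are
  packaged defaults exposed as configuration.
* Scenario results are emitted in long/tidy form
  (`scenario,parameter,factor,time,species,value`) so any plotting layer
  can reproduce the sweep figures without bespoke reshaping; sweeps reuse
  one base model and vary only the swept parameter, so cross-run
  differences are attributable to it alone.
* The SBML Level 3 export is written directly against the schema (species,
  constant rate parameters, the three fluxes as assignment rules, rate
  rules in content MathML, the death floor as a piecewise).  The
  zero-boundary projection is an integrator feature and is not encoded in
  the document.

## Known limitations and deviations

* **No aggregation, space, or stochasticity.** Aβ
  nucleation/fibril/plaque kinetics, spatial or agent-based variants, and
  Gillespie-type simulation are out of scope, as is parameter estimation
  from data.
* **Baseline M1 drift.** Under the reconstruction the baseline M1
  derivative is negative (−199/yr at t = 0) and the reactive pool drains
  to the zero boundary near year 19, whereas the qualitative expectation
  for the healthy baseline is a relatively stable microglial population.
  This is the main place the reconstructed trajectories deviate
  qualitatively; it cannot be resolved without the original algebra.
* **Sweep magnitudes.** A tenfold increase of the Aβ→M1 activation rate
  multiplies N_d(20) by ≈9.5 under the reconstruction, well above the
  reported near-doubling; the check is therefore a flagged (warning), not
  failing, band.  All reported sweep *directions* (monotone dose-response
  in both sweeps, Aβ falling as activation rises, exact α8/α13
  interchangeability) are reproduced.
* **Rate-sensitivity magnitudes.** The normalization behind the published
  rate-sensitivity magnitudes is unstated and could not be confirmed by
  desk arithmetic, so they are treated as sign/rank anchors only; the
  initial-condition coefficients, by contrast, are reproduced numerically
  to the printed precision.
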