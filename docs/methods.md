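# Methods

## The model

`cpebswitch` implements a positive feedback loop between the kinase
αCaMKII and its translational regulator CPEB1.  αCaMKII exists in an
inactive form X and an active, phosphorylated form X_P; CPEB1 in an
unphosphorylated form Y and a phosphorylated form Y_P.  Six elementary
reactions close the loop:

| reaction | scheme | rates |
|---|---|---|
| R1 | X + Ca₄CaM ⇌ X_P | k₁₀, k₁₀₁₀ |
| R2 | X + X_P ⇌ C₁ → 2 X_P | k₁, k₂, k₃ |
| R3 | X_P + P → X + P | k₄ |
| R4 | Y + X_P ⇌ C₂ → Y_P + X_P | k₅, k₅₅, k₆ |
| R5 | Y_P + P → Y + P | k₇ |
| R6 | Y_P + T ⇌ C₃ → Y_P + X + T | k₈, k₈₈, k₉ |

R6 models translation: phospho-CPEB1 bound to the translation machinery T
(the complex C₃) catalyses synthesis of new, inactive kinase — the step by
which cytoplasmic polyadenylation feeds activity back into protein
abundance.  Free X and X_P relax toward small basal levels at degradation
rates λ₂ and λ₁; **complexes do not degrade**, a detail that drives all the
interesting discrepancies between the full model and its reductions.

Mass action over R1–R6 gives six ODEs in (X, X_P, Y_P, C₁, C₂, C₃).  Free
CPEB1 is carried by the exact conservation Y = Y_T − Y_P − C₂ − C₃ rather
than as a seventh equation; the test suite integrates an explicit-Y
variant as an independent oracle and confirms conservation to 1e-8
relative.  One sign pair in the activation fluxes of the dX/dt equation is
implemented as R1's stoichiometry dictates (−k₁₀·X·U + k₁₀₁₀·X_P), the form
consistent with the dX_P/dt equation.  The readout of the switch is the
total kinase concentration

    X_T = X + X_P + 2 C₁ + C₂ .

Ca₄CaM (U) is an exogenous input, not a dynamical variable; there is no
upstream calcium model and no stochastic simulation.

### Units

Concentrations in μM, time in s.  Second-order rate constants are
μM⁻¹s⁻¹; this package treats k₃ as first-order (s⁻¹) and k₄, k₇ as
second-order (paired with the phosphatase pool P), which is the only
dimensionally consistent reading of the scheme — P₇ = k₇·P and P₄ = k₄·P
are then rates and P₇/a a concentration.

## Staged reductions

**3-ODE model.**  The complexes equilibrate within milliseconds
(1/(k₂+k₃) ≈ 2 ms at condition I), so a pseudo-steady-state assumption
eliminates them: C₁ = k₁XX_P/(k₂+k₃), C₂ = k₅YX_P/(k₅₅+k₆),
C₃ = k₈Y_PT/(k₈₈+k₉).  With Y ≈ Y_T − Y_P the system closes in
(X_T, X_P, Y_P):

    dX_T/dt = k₉C₃ − λX_T
    dY_P/dt = −k₇P·Y_P + a(Y_T − Y_P)X_P ,   a = k₅k₆/(k₅₅+k₆)
    dX_P/dt = X(a₁X_P + k₁₀U) − (P₄+k₁₀₁₀)X_P ,  a₁ = k₃k₁/(k₂+k₃)

with X recovered algebraically from the composition.  The X_T equation is
the load-bearing approximation: it degrades the *total* pool, complexes
included, at the single rate λ (= λ₁ = λ₂; unequal rates are rejected for
reduced-model use).  It is accurate exactly when little kinase is
complex-bound.

**1-D model.**  Setting dY_P/dt = 0 gives the saturating nullcline
Y_P = aY_TX_P/(P₇ + aX_P) (half-max at X_P = P₇/a); setting dX_P/dt = 0
gives a monotone map X_T = f(X_P).  Numerically inverting f as
X_P = h(X_T) collapses everything onto

    dX_T/dt = G'(X_T) − F(X_T),   G' = c·h/(h + P₇/a),   F = λX_T ,

with c = k₉k₈TY_T/(k₈₈+k₉) the saturated synthesis rate.  Fixed points are
the intersections of the synthesis curve G' with the degradation line F:
generically one (basal) or three (basal, separatrix, up state).

**Steady-state polynomial.**  Substituting both nullclines into the
synthesis–degradation balance and clearing the two rational denominators
(a₁X_P + a₂) and (aX_P + P₇) yields a polynomial with zero constant term —
X_P = 0 is always a steady state.  After cancelling the common factor
(aX_P + P₇) shared by the synthesis term and the CPEB1-complex term, the
exact eliminant is a *cubic* times X_P.  The package exposes it in quartic
form by retaining that common factor; the extra root sits at
X_P = −P₇/a < 0 and never passes the non-negativity filter.  This mirrors
the historical four-denominator elimination of this system, whose published
closed-form coefficients contain two typographical defects (a dropped
factor k₆ ≈ 0.962 in one term, and an undefined symbol in the z-coefficient
ladder); `compare_printed_quartic` evaluates the published ladder under
every plausible reading of the undefined symbol and reports — never
averages — the mismatch.  A dense-scan oracle over the balance function
confirms the eliminated polynomial's roots to 1e-6 relative.

### The inversion fit

h is a degree-9 polynomial in X_T with zero intercept (so h(0) = 0
exactly), fitted by unweighted least squares on a mixed grid of 500 X_P
points — half geometric from 1e-4 μM, half linear — mapped through f, over
[0, 1.5 × upper fixed point].  The basis is evaluated in X_T/scale to keep
the Vandermonde matrix conditioned.  f is nearly a ramp: flat at the
X_P-loss plateau DI/a₁ ≈ 9.4 μM, then linear.  A degree-9 polynomial
cannot follow the knee of the inverse exactly, so the fit's validity floor
`domain_lo` (the smallest X_T above which the round trip f(h(X_T))
stays within 2%) sits above the knee, and the basal shoulder of the 1-D
model is only qualitatively captured — the lower stable state is recovered
through the exact h(0) = 0, not through fit accuracy.  Inside `G'` the
fitted h is clamped below at zero so synthesis can never go negative.
With this protocol the 1-D fixed points land within 1% of the
quartic-level ones on all three branches.

## Free concentrations and calibration

The rate table fixes every kinetic constant but not the pools P
(phosphatase), T (translation machinery), Y_T (total CPEB1) or the resting
Ca₄CaM level.  Two observations reduce this freedom:

* at the reduced levels T and Y_T enter (almost) only through the product
  c ∝ T·Y_T, and
* P sets both the CPEB1 half-saturation P₇/a and the X_P-loss plateau.

So exactly two effective scalars — the c-group T·Y_T and P — are fitted by
deterministic bounded least squares (no seeds, no randomness) to the two
condition-I baseline fixed points, upper X_T = 95 μM and separatrix
X_T = 9.4 μM at λ = 1e-4 s⁻¹.  The upper target is matched exactly through
the c-group; the separatrix is floored at DI/a₁ ≈ 9.41 + O(P), so the fit
presses P to its physiological lower bound (0.01 μM within the allowed
[0.01, 100]).  Result: T·Y_T = 15.027 μM², P = 0.01 μM, residuals
0.003% and 0.58%.  Every other number the package reproduces — the fixed
points at λ = 3e-4 s⁻¹, at k₅ = 1e-4 μM⁻¹s⁻¹, the full-model trapping
state, the bistable ranges — is out-of-sample with respect to this
calibration.

The split of the product is a modeling choice, frozen at Y_T = 15 μM and
T ≈ 1.0 μM: it keeps CPEB1 sequestration into C₃ below 1% of Y_T, which is
what lets the full model and the reductions agree in condition I (a
machinery-heavy split visibly depresses the full model's upper state by
trapping phospho-CPEB1).  U_basal = 1e-6 μM, effectively zero, keeps the
resting state at the basal level while still seeding the activation
reaction.

Known mismatch: with this two-scalar family no value of P reproduces both
published k₅ = 1e-4 fixed points simultaneously — matching the upper state
(70 μM) requires small P, matching the separatrix (16 μM) larger P, and the
two requirements cross outside a joint ±10% window.  The frozen
configuration predicts 64.7 and 13.9 μM; the separatrix value is therefore
reported as a known deviation rather than tuned for.

## Conditions and stimulus protocols

Condition I (k₃ = 500 s⁻¹) and condition II (k₃ = 0.5 s⁻¹) differ only in
the autophosphorylation rate.  In condition I almost no kinase is
complex-bound and all four model levels share the same three fixed points
(within 1%).  In condition II roughly ¾ of the kinase at the up state sits
in the C₁ complex, which the reductions degrade (through λX_T) but the
full model does not: the full model's upper state rises to ≈357 μM while
the reductions stay near 94 μM.  This is the designed failure mode of the
X_T-equation approximation.

Stimuli are square Ca₄CaM pulses (default: 10 s at U_stim = 10 μM starting
at t = 10 s), integrated with the pulse edges as hard breakpoints.  A
quantitative constraint shapes the up-state protocol: starting from the
resting state (total kinase ~1e-4 μM), *no* pulse amplitude can switch the
loop on within 10 s.  Crossing the separatrix requires phospho-CPEB1 of
order 0.1·Y_T, but phospho-CPEB1 production is bounded by a·X_P·Δt with
X_P capped by the resting pool plus at most c·Δt ≈ 0.1 μM of new synthesis
— four orders of magnitude short, for any amplitude.  Up-state runs
therefore start from a supra-threshold pool of *inactive* kinase (2× the
separatrix X_T, delivered as free X) and use the pulse for what it can do:
seed the activation that ignites autophosphorylation.  Down-state runs
start at the basal state and stay there through any pulse, which the
amplitude-threshold search reports as "no threshold".

## Numerical choices

* **Integration**: LSODA with rtol 1e-8, atol 1e-12 μM (the basal and
  upper states span six decades); trajectories clipped at zero within a
  −1e-9 μM slack, larger excursions abort.  Steady-state runs integrate to
  50/λ (5e5 s at baseline), which closes the slow final approach of the
  condition-II trapping state (its X_T is within 0.01 μM of the root-solved
  fixed point at that horizon).
* **Root solving**: quartic roots via the companion matrix
  (`numpy.polynomial`); imaginary parts tolerated to 1e-9 relative,
  negatives above −1e-12 snapped to zero.  reduced3/full fixed points by
  multi-start Powell-hybrid (`scipy.optimize.root`) seeded from the
  quartic roots, the basal state and a geometric X_P ladder; accepted only
  when max|RHS| < 1e-9 μM/s.  No point is ever fabricated: an empty result
  is returned as such.
* **Stability**: sign of the leading eigenvalue of the central-difference
  Jacobian (full/reduced3), of the 1-D slope (one_d), or of the balance
  derivative along the nullcline manifold (quartic); |eigenvalue| < 1e-10
  s⁻¹ is labelled marginal.
* **Branches and sweeps**: dense-grid continuation (200 points; linear in
  λ over [2e-5, 1e-3] s⁻¹, logarithmic in k₅ over [1e-5, 1e-1] μM⁻¹s⁻¹)
  with nearest-XT branch matching (threshold |ΔX_T|/(1+X_T) = 0.25);
  saddle-nodes refined by bisection to 1e-3 relative in the parameter.
  Fixed points closer than 0.5 μM absolute are treated as one branch, which
  also absorbs the basal-state ambiguity (reduced levels put it at exactly
  0, the full model at X_basal = 1e-4).
* **Quasi-static hysteresis probes** integrate 30/λ at each parameter step
  from the previous step's end state, at the reduced3 level.

## What the synthetic conditions do and do not emulate

All inputs are parameter configurations and pulse protocols; there is no
experimental time-series data in this problem, so "synthetic data" means
the condition-I/II parameter sets, the frozen calibrated pools, stimulus
protocols, and seeded log-uniform perturbation ensembles for robustness
scans.  Passing tests therefore demonstrate internal consistency of the
model family and reproduction of its published steady-state structure —
not that a synapse holds these concentrations.  In particular the absolute
pool sizes (P, T, Y_T) are calibration artifacts constrained only through
two effective scalars, the two-state kinase is a deliberate simplification
of holoenzyme biology, and degradation lumps proteolysis and diffusion
into one first-order rate.

## Known limitations

* The separatrix at lowered CPEB1 activation (k₅ = 1e-4) lands at 13.9 μM
  against a published 16 μM; see the calibration section.
* The λ saddle-node falls at 7.1e-4 s⁻¹ with the frozen calibration, so
  the system is still (barely) bistable at λ = 6e-4 s⁻¹ where the
  published synthesis/degradation graphs show mono-stability.
* The degree-9 inversion is unreliable below its `domain_lo` (≈13 μM at
  baseline); 1-D-level results on the basal shoulder rest on the exact
  zero intercept, not on fit accuracy.
* `switching_threshold` over pulse amplitude correctly reports that no
  amplitude switches the loop from rest (see the stimulus section); pool
  and duration families are the informative ones.
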