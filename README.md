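# cpebswitch

A tested Python implementation of the CPEB1–αCaMKII cytoplasmic-
polyadenylation loop as a bistable biochemical switch, for modelers in
synaptic plasticity and systems biology who want the full mass-action
model, its analytical reductions, and the resulting bifurcation structure
in one reproducible package.

## The science

Active, phosphorylated αCaMKII (X_P) phosphorylates the translational
regulator CPEB1 (Y → Y_P); phospho-CPEB1 bound to the translation
machinery drives polyadenylation-dependent synthesis of new, inactive
αCaMKII (X).  Synthesis feeds back on kinase abundance while degradation
(rate λ) drains it, and the balance

    dX_T/dt = G'(X_T) − λ·X_T ,   G'(X_T) = c·h(X_T) / (h(X_T) + P₇/a)

between the saturating synthesis function G' and linear degradation admits
either one fixed point (basal) or three (basal, separatrix, up state):
a bistable switch whose up state can store an activity-induced rise in
kinase concentration indefinitely.  The package implements this system at
four nested levels and proves their relationships against each other:

* **full** — six mass-action ODEs in (X, X_P, Y_P, C₁, C₂, C₃), with free
  CPEB1 carried by exact conservation;
* **reduced3** — pseudo-steady-state elimination of the complexes, three
  ODEs in (X_T, X_P, Y_P);
* **one_d** — the single synthesis–degradation ODE above, built on a
  degree-9 zero-intercept polynomial inversion X_P = h(X_T);
* **quartic** — the steady-state polynomial in X_P (zero constant term, so
  X_P = 0 is always a root) whose non-negative roots are the fixed points.

Fixed points are classified by Jacobian eigenvalues, switching experiments
integrate 10-s Ca₄CaM pulses, and bifurcation diagrams are built over the
degradation rate λ and the CPEB1-activation rate k₅, including saddle-node
locations, bistable ranges and hysteresis.  `docs/methods.md` documents
the model, the calibration of the free concentrations, and every numerical
choice.

## Worked example

```python
import cpebswitch as cs

params = cs.make_condition("I")        # frozen reference, k3 = 500/s
cmp = cs.compare_levels(params)
print(cmp["table"].to_string(index=False))
```

```
 branch    ref_XT model_level        XT  discrepancy stability
      0  0.000000        full  0.000100 1.000000e-04    stable
      0  0.000000    reduced3  0.000000 0.000000e+00    stable
      0  0.000000       one_d  0.000000 0.000000e+00    stable
      0  0.000000     quartic  0.000000 0.000000e+00    stable
      1  9.454857        full  9.456073 1.286383e-04  unstable
      1  9.454857    reduced3  9.454857 1.878777e-16  unstable
      1  9.454857       one_d  9.378314 8.095597e-03  unstable
      1  9.454857     quartic  9.454857 0.000000e+00  unstable
      2 95.002635        full 94.515963 5.122715e-03    stable
      2 95.002635    reduced3 95.002635 0.000000e+00    stable
      2 95.002635       one_d 95.002343 3.066427e-06    stable
      2 95.002635     quartic 95.002635 0.000000e+00    stable
```

Three fixed points per level: the basal down state, the separatrix near
9.45 μM, and the up state near 95 μM total αCaMKII, with all four model
levels agreeing within 1% — condition I is the regime where the reductions
are valid.  Rebuilding with `cs.make_condition("II")` (slow
autophosphorylation, k3 = 0.5/s) traps most kinase in complexes that the
reductions degrade but the full model does not: the full model's up state
rises to ≈357 μM while the reduced levels stay near 94 μM.

A switching experiment and a bifurcation sweep:

```python
proto = cs.make_stimulus()                       # 10-s Ca4CaM pulse
y0 = cs.up_state_initial(params, "full")         # supra-threshold pool
traj = cs.integrate(params, y0, proto, 5e5, "full")
print(traj.xt[-1])                               # -> 94.51596...

import numpy as np
diagram = cs.sweep(params, "k5", np.geomspace(1e-5, 1e-1, 200))
print(cs.bistable_range(diagram))                # -> (6.08e-05, 0.1, 3.216)
```

The same operations are available from the shell via the `cpebswitch` CLI
(`calibrate`, `fixed-points`, `simulate`, `bifurcate`, `fit-inversion`,
`compare-levels`).

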