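# stopflow

Pre-steady-state kinetics of the Diels–Alderase **AbyU** — an enzyme that
catalyses an intramolecular [4+2] cycloaddition, converting a linear triene
substrate (absorbing at 325 nm, ε = 13 200 M⁻¹ cm⁻¹) into a spirotetronate
product (ε = 1085 M⁻¹ cm⁻¹). The loss of the chromophore on cyclisation
makes the reaction observable by stopped-flow absorbance.

The package is for enzymologists who want to simulate, deconvolve and
re-analyse stopped-flow transients of this reaction cycle:

* **`stopflow.scheme`** — a stiff mass-action ODE model of the full cycle
  with three resolvable binding conformations:

  ```
  E + S ⇌ ES    (k1 / k−1)   productive; ES → EP at k5 (fast cyclisation)
  E + S ⇌ ES2   (k2 / k−2)   sub-optimal; rearranges ES2 ⇌ ES (k4 / k−4)
  E + S ⇌ ES3   (k3 / k−3)   non-productive dead end
  EP → E + P    (k6)         rate-limiting product release
  S → P         (k_spont)    uncatalysed background cyclisation
  ```

  plus Beer–Lambert projection to A₃₂₅(t) and the derived dissociation
  constants K₁ = k₋₁/k₁, …, K₄ = k₋₄/k₄ and K_app = K₂·K₄.
* **`stopflow.synth`** — seeded, instrument-realistic synthetic transients
  (logarithmic/linear timebases, 2 ms dead time, additive Gaussian noise,
  optional substrate loss to the flow tubing) in the three experimental
  regimes: single turnover (400 μM enzyme ≫ substrate), multiple-turnover
  burst (1 μM enzyme, up to 54 μM substrate) and uncatalysed controls.
* **`stopflow.fitting`** — multi-exponential deconvolution
  A(t) = Σᵢ Aᵢ·exp(−k_obs,i·t) + c (+ b·t), with multi-start
  variable-projection initialisation, phase-count selection (corrected
  information criterion + residual runs test), burst fitting, tail linear
  fits and absorbance↔concentration conversion.
* **`stopflow.analysis`** — concentration-dependence fits: one-step binding
  (k_obs = k_on[S] + k_off), Haldane substrate inhibition
  (k_obs = k_max·S/(K_m + S(1+S/K_i))), the two-step binding slow
  eigenvalue k_obs = ½(p − √(p²−4r)), Michaelis–Menten steady state
  (v/E₀ = k_cat·S/(K_m+S)), spontaneous-rate estimation, background
  subtraction and assembly of the full constant table with provenance.
* **`stopflow.pipeline` / `stopflow` CLI** — the end-to-end experiment:
  simulate → fit → analyse → score parameter recovery against the known
  generating constants.

A set of experimentally determined constants (k₁ = 0.88 μM⁻¹ s⁻¹,
k₋₁ = 3.41 s⁻¹, k₆ ≈ 0.12 s⁻¹, k_spont = 1.25×10⁻³ s⁻¹, …) ships with the
package (`RateConstants.abyu_defaults()`).

## Worked example

```python
import numpy as np
from stopflow import (
    RateConstants, OpticalModel, TimebaseSpec, NoiseSpec,
    generate_transient, truncate_dead_time, select_n_phases,
    estimate_initial_concentration, derived_constants,
)

rc = RateConstants.abyu_defaults()
om = OpticalModel()

# one single-turnover transient: 400 uM enzyme vs 25 uM substrate,
# logarithmic 1000 s timebase, 2 ms dead time, 0.002 AU noise
tb = TimebaseSpec("logarithmic", duration=1000.0, cycles=15, points_per_cycle=200)
transient = generate_transient(rc, om, E0=400.0, S0=25.0, tb=tb,
                               noise=NoiseSpec(sigma=0.002, seed=42))
transient = truncate_dead_time(transient)

selection = select_n_phases(transient)
fit = selection.best
print(f"phases selected: {selection.n_selected}")
for i, (a, k) in enumerate(zip(fit.amplitudes, fit.rates), 1):
    print(f"  phase {i}: kobs = {k:8.3f} /s   amplitude = {a:+.4f} AU")
print(f"S0 from A(t=0): {estimate_initial_concentration(transient, om, fit=fit):.1f} uM")
print(f"K1 = {derived_constants(rc).K1:.3f} uM")
```

prints

```
phases selected: 3
  phase 1: kobs =  423.697 /s   amplitude = -0.0559 AU
  phase 2: kobs =  102.177 /s   amplitude = +0.2681 AU
  phase 3: kobs =    1.835 /s   amplitude = +0.0942 AU
S0 from A(t=0): 25.3 uM
K1 = 3.875 uM
```

Three exponential phases are required, as with the real instrument data.
The fast pair is the productive-route relaxation (the negative amplitude is
the short lag while ES builds up before cyclising); the ~1.8 s⁻¹ phase is
conversion through the sub-optimal conformation ES2. The fitted A(t = 0)
recovers the delivered substrate concentration, which is how starting
concentrations are measured in practice.

The same workflow from the shell:

```bash
stopflow recover --seed 0 --report recovery_report.json
stopflow simulate --out data/ && stopflow fit --manifest data/multiple_turnover/manifest_multiple_turnover.json
```

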