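# inhibkit

Kinetic inference and hit-to-lead triage for enzyme-inhibitor discovery,
built around the assay work-up used for methoxyacrylate (MOA) inhibitors of
the respiratory cytochrome *bc*₁ complex (ubiquinol–cytochrome *c*
oxidoreductase), the target of strobilurin fungicides such as azoxystrobin.

The package covers three layers of that work-up:

* **Slow-binding progress-curve analysis.** An inhibitor that equilibrates
  slowly with its enzyme produces product traces that start linear and bend
  toward a steady state.  Each trace at fixed substrate concentration [S]
  and inhibitor concentration [I] follows the one-step integrated equation

      P(t) = v_s·t + (v₀ − v_s)·(1 − e^(−k_obs·t))/k_obs

  with initial rate v₀, steady-state rate v_s and observed first-order
  constant k_obs.  Titrating the inhibitor gives a straight line
  k_obs = B + A·[I]; the substrate dependence of the apparent association
  constant A (slope) and dissociation constant B (intercept) diagnoses the
  binding modality (A falling with [S] at flat B ⇒ competitive), and the
  microscopic constants follow from 1/A = (1/k₊₀)(1 + [S]/K_m), k₋₀ = B,
  and K_i = k₋₀/k₊₀.

* **Classical (fast-binding) inhibition analysis.** Initial-rate grids over
  (S, I) are fitted globally to the four Michaelis–Menten inhibition laws
  (competitive, noncompetitive, uncompetitive, mixed) by weighted nonlinear
  least squares with AICc model selection, plus Lineweaver–Burk
  double-reciprocal diagnostics and apparent-parameter trends
  (K_m,app = K_m(1 + [I]/K_i) for a competitive inhibitor).

* **Hit-to-lead triage.** Free-energy conversions ΔG = RT·ln K_i,
  ΔΔG = RT·ln(K_i,new/K_i,ref), fold improvement, ligand efficiency
  LE = −ΔG/N_heavy; enumeration of the 80 ring-substitution candidates
  (2 scaffold series × 4 sites × 10 groups); the ΔΔG < −1.37 kcal/mol
  selection criterion (a 10-fold potency gain at 300 K); and the six-rule
  pesticide-likeness filter (MW ≤ 435 Da, ClogP ≤ 6, HBA ≤ 6, HBD ≤ 2,
  rotatable bonds ≤ 9, aromatic bonds ≤ 17).

A seeded synthetic-assay generator reproduces the two assay systems of the
study (succinate–cytochrome *c* reductase with cytochrome *c* varied, and
the decylubiquinol DBH₂–cytochrome *c* system) so every stage of the
inference chain is testable without laboratory data.

## Worked example

```python
import inhibkit as ik
from inhibkit.simulate import (GeneratorSpec, LEAD_CYTC_SLOW_DESIGN,
                               LEAD_CYTC_SLOW_TRUTH, generate_progress_curves)

spec = GeneratorSpec("slow-binding-noncompetitive", LEAD_CYTC_SLOW_TRUTH,
                     LEAD_CYTC_SLOW_DESIGN, "additive", sigma=0.0, seed=0)
curves, truth = generate_progress_curves(spec)
an = ik.SlowBindingAnalyzer(modality="noncompetitive").fit(curves)
print(f"k+0 = {an.constants_.k_plus0_per_nM:.5f} /s/nM")
print(f"k-0 = {an.k_minus0_:.5f} /s")
print(f"Ki  = {an.Ki_*1e9:.1f} nM")
```

prints

```
k+0 = 0.00066 /s/nM
k-0 = 0.00271 /s
Ki  = 4.1 nM
```

i.e. a noiseless titration at the fixed-substrate design returns exactly the
generator's association and dissociation constants, and their ratio — the
inhibition constant of the slow-binding lead — is 4.1 nM.  Thermodynamic
one-liners work the same way: `ik.fold_improvement(297.6e-9, 4.1e-9)`
returns 72.6 (the ≈73-fold potency gain of the lead over azoxystrobin) and
`ik.ddG_from_ki(ki/10, ki)` returns −1.37 kcal/mol.

The same pipeline is scriptable from a shell:

```
inhibkit simulate --design lead-cytc-slow --seed 1 --out run/
inhibkit slowbind run/progress.csv --modality noncompetitive --out run/slow.json
inhibkit fit-rates run/rates.csv --out run/fit.json      # fast-binding grids
inhibkit triage candidates.csv --threshold -1.37 --out run/selected.csv
```

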