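# Methods

## Scope and model assumptions

The package analyses inhibition of a Michaelis–Menten enzyme by two classes
of inhibitor:

* **Fast-binding** inhibitors equilibrate instantly on the assay timescale;
  initial rates over a (substrate, inhibitor) grid obey one of the four
  classical laws (competitive, noncompetitive, uncompetitive, mixed with
  separate K_ic/K_iu).
* **Slow-binding** inhibitors follow the one-step scheme
  E + I ⇌ EI with association rate k₊₀[I] and dissociation rate k₋₀, the
  EI complex being catalytically dead.  The occupancy relaxes exponentially
  with k_obs, giving the integrated trace
  P(t) = v_s·t + (v₀−v_s)(1−e^(−k_obs t))/k_obs.  The two-step
  (isomerisation) mechanism and tight-binding depletion corrections are out
  of scope: a single (k₊₀, k₋₀) pair is assumed to describe the data, and
  v₀ is the uninhibited-equivalent initial rate (no fast initial complex,
  consistent with the linear onset of the traces analysed).

Consequences used throughout, and enforced by tests:

* k_obs = k₋₀ + k₊₀[I]/(1+[S]/K_m) (competitive) or k₋₀ + k₊₀[I]
  (noncompetitive); the two coincide at [S] = 0.
* v_s = v₀/(1 + [I]/K_i,app) with K_i,app = K_i(1+[S]/K_m) for the
  competitive case — the generator and the forward model satisfy this
  identity exactly.
* K_i = k₋₀/k₊₀, computed exactly as that ratio.

Internal units are molar, seconds, and molar/s (signal units are arbitrary
but consistent); the I/O layer converts the μM/nM columns used in assay
tables, and reported constants follow assay conventions (K_i in nM, k₊₀ in
s⁻¹ nM⁻¹).

## Progress-curve fitting

Each trace is fitted by nonlinear least squares (`scipy.optimize
.least_squares`, trust-region reflective) in normalized coordinates — time
in units of the trace length, signal in units of its maximum — which keeps
the three parameters at comparable scale regardless of the instrument's
signal magnitude.  Five deterministic starts are used: k_obs ∈
{0.5, 1, 2, 5, 10}/T_end, v₀ seeded by the secant slope over the first
decile of points and v_s over the last quintile.  The best SSE wins; ties
break toward smaller k_obs.  Standard errors come from the Jacobian at the
optimum (σ² estimated from the residual SSE with n−3 degrees of freedom).

A trace with no detectable slow phase is reported as linear rather than
with an arbitrary k_obs: the three-parameter fit is compared with a
straight line through the origin by an F-test (2, n−3); at p > 0.05 the fit
result is a sentinel with v₀ = v_s = the line slope and k_obs undefined.  A
numerically exact line (residuals at floating-point level) short-circuits
the test.  Traces at [I] = 0 are expected to take this path.

## The k_obs chain and modality diagnosis

At every substrate level with at least three usable inhibitor levels,
k_obs is regressed on [I] by unweighted OLS (the apparent constants are
conventionally read off a simple straight-line titration; inverse-variance
weighting of the pooled quantities is applied downstream instead).

Modality is diagnosed from the substrate dependence of the apparent
constants, which requires ≥ 3 substrate levels:

* *competitive*: the slope of 1/A on [S] is significantly positive
  (one-sided t-test, α = 0.05) **and** B is invariant — no significant
  trend (two-sided, α = 0.05) and a practical-equivalence band of
  |ΔB|/mean(B) < 20 % across the range.  The dual test reflects that
  invariance is asserted, not just non-rejected.
* *noncompetitive*: no significant [S]-dependence of the k_obs line.
* anything else, or fewer than three substrate levels: *undetermined*,
  with the full evidence (slopes, p-values, relative ranges) attached.

With only four or five substrate levels the trend t-test has few degrees of
freedom: under noisy data the classifier is deliberately conservative (it
under-calls "competitive"; its type-I rate under noncompetitive truth is
bounded well below α in simulation), and studies designed with a single
substrate level must force the modality explicitly.  This mirrors practice:
the single-substrate titration is interpreted under an independently
established modality.

Microscopic constants: k₋₀ is the inverse-variance weighted mean of the B
intercepts (plain mean when standard errors are unavailable).  For a
noncompetitive inhibitor k₊₀ is the pooled A.  For a competitive one
1/A = (1/k₊₀)(1+[S]/K_m): with K_m known the line is forced through the
origin in the regressor x = 1+[S]/K_m (least squares for 1/k₊₀); with K_m
unknown both constants are read off the free 1/A-vs-[S] line.  Non-positive
derived constants raise an inconsistent-data error rather than propagate.

## Steady-state fitting and model selection

All four laws are fitted globally to the untransformed rates in
log-parameter space (which enforces positivity without constrained
optimisation), with residuals weighted 1/v by default — the constant-CV
error model typical of enzymatic rate data; unweighted fitting is an
option.  Three starts over the K_i scale guard against local minima.

Selection uses AICc with n = number of rate observations and k = number of
kinetic parameters + 1 (residual variance).  Because exact fits make
log(SSE) unbounded, SSE is floored at n·(10⁻¹² × data scale)², so any model
whose residuals are at numerical-noise level is treated as exact and the
comparison falls back to the parameter penalty.  The mixed law nests the
other three, so on clean data it ties the true simple law up to that
penalty (ΔAICc ≈ 2.5, never > 10); the selection rule is therefore: among
models within ΔAICc < 2 of the best, prefer the fewest parameters, and
report "undetermined" only for a same-complexity tie.  The wrongness margin
quoted in reports and asserted in tests (> 10 on noiseless data) is taken
over the laws that do **not** nest the selected one.

Lineweaver–Burk diagnostics are provided for the classical plot reading —
a common 1/v-axis intercept (competitive), a common 1/[S]-axis intercept
(noncompetitive), parallel lines (uncompetitive) — classified by the
pattern whose characteristic quantity has the smallest relative spread,
accepted either below a strict tolerance or within two pooled standard
errors.  Because the reciprocal transform is biased under proportional
noise (tested explicitly), the nonlinear fit is always the report of
record.

## Triage layer

ΔG = RT·ln K_i with K_i in molar and R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹,
T = 300 K by default, which makes RT·ln 10 = 1.373 and the 10-fold
criterion −1.37 kcal/mol at two decimals; T is configurable.  The triage
threshold is strict ("lower than"): a shift of exactly −1.37 is excluded.
Candidate numbering is series-major, then site 4→7, then group a→j,
starting at 2 — the ordering consistent with the printed ranges 2–41 and
42–81 — and is recorded in output metadata.  Descriptors (MW, ClogP, HBA,
HBD, rotatable bonds, aromatic bonds) are consumed as inputs, never
computed from structures.  Report rounding: K_i to 1 decimal in nM, ΔΔG and
LE to 2 decimals; raw doubles are preserved in JSON.

## Synthetic data

The generator reproduces the study's assay designs as shipped defaults:

| design | grid | truth |
|---|---|---|
| `AZ_DBH2_DESIGN` | DBH₂ 20–120 μM × AZ {0, 500, 1000, 2000, 3000, 5000} nM | competitive, K_m = 80 μM, K_i = 394.7 nM |
| `HIT_CYTC_DESIGN` | cyt *c* 1.13–15.6 μM (6 log-spaced levels) × {0, 10, 20, 40, 60} nM | noncompetitive, K_m = 4.3 μM, K_i = 31.1 nM |
| `HIT_DBH2_DESIGN` | DBH₂ 20–120 μM × {0, 50, 100, 200, 300, 500} nM | competitive, K_i = 96.5 nM |
| `LEAD_CYTC_SLOW_DESIGN` | cyt *c* 60 μM; inhibitor {0, 15, 20, 30, 40, 50} nM | slow noncompetitive, k₊₀ = 0.00066 s⁻¹nM⁻¹, k₋₀ = 0.00271 s⁻¹ |
| `LEAD_DBH2_SLOW_DESIGN` | DBH₂ {20, 40, 80, 120} μM with scaled titrations | slow competitive, k₊₀ = 0.00038 s⁻¹nM⁻¹, k₋₀ = 0.00509 s⁻¹, K_m = 80 μM |

Where a printed design gives only ranges, the defaults declare a concrete
choice: six log-spaced substrate levels for the 1.13–15.6 μM range, and for
the slow competitive study four substrate levels whose inhibitor titrations
interpolate the two printed endpoint grids ({20,40,60,80} nM at 20 μM,
{40,80,120,180} nM at 120 μM; top level = S/μM + 60 nM, quarter spacing).
Progress curves span 600 s at 60 points, ≥ 3/k_obs for every on-grid
condition so the steady-state rate is identifiable; a grid point with
k_obs·duration < 1 triggers a warning.

Noise defaults: rate tables get proportional Gaussian noise with σ = 3 %
(constant CV, matching the fit weighting); progress curves get additive
Gaussian noise with σ = 2 % of each curve's final signal.  Randomness is
numpy's default PCG64 generator seeded from the `GeneratorSpec`, so a fixed
spec reproduces byte-identical data.

The generator emulates the designs' statistical structure, not instrument
physics: no baseline drift, no enzyme/inhibitor depletion, no substrate
consumption within a trace.  Passing recovery tests therefore demonstrate
that the inference chain is correct and unbiased under its own assumptions
at realistic noise — not that those assumptions hold for any particular
spectrophotometer record.

## Reported recovery runs

`scripts/acceptance.py` runs 100 seeded replicate studies per design
(sub-seeds drawn from a `SeedSequence` of the user seed) and reports mean
recovered constants: fitted K_m and K_i at the competitive rate-grid
design, fitted K_i at the noncompetitive design, the mean k_obs-titration
slope at the fixed-substrate slow-binding design, and the mean k₊₀ from
the full competitive slow-binding chain with K_m fixed at its assay value.
In the competitive slow-binding chain a replicate whose pooled dissociation
intercept is driven negative by noise raises the inconsistent-data error
and is excluded (reported n counts the studies used; ~1 % of replicates).

## Known limitations

* One-step slow-binding only; a genuine two-step inhibitor would show
  hyperbolic k_obs-vs-[I] curvature that this package would mis-read as a
  line over a narrow titration.
* The modality trend tests have low power at ≤ 4 substrate levels; they
  bound false "competitive" calls but frequently return "noncompetitive"
  or "undetermined" on noisy competitive data.  Designs intending a
  modality call should titrate more substrate levels.
* K_i,app-based identities assume no inhibitor depletion ([I] ≫ [E]).
* Uncertainties are per-stage (Jacobian or OLS); no error propagation
  across the full chain is attempted beyond inverse-variance pooling.
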