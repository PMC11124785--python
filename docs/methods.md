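# Methods

## The model

`clopk` implements a joint population pharmacokinetic model for oral
clopidogrel (CLO, the parent pro-drug) and its inactive carboxylic-acid
metabolite (CLO-CA), the dominant circulating species.  The structural model
is linear and time-invariant between dose events:

* **Absorption.**  A depot followed by two transit compartments, all with
  the same rate constant `K_tr = (n_transit + 1)/MTT` (Erlang-type delay).
  `MTT` is the mean transit time in hours and is study-specific.
* **Hepatic first pass.**  Absorbed drug enters a liver compartment of
  physiological volume `V_h = 1.5 L/70 kg` that empties at the plasma-flow
  rate `Q_h/V_h` with `Q_h = 50 L/h`.  The outflow is partitioned by the
  dose fractions: a fraction `F_P` continues into the systemic parent
  circulation, `F_iaM` is converted to CLO-CA (the flux is multiplied by
  the metabolite/parent molecular-weight ratio 0.9565), and `F_aM` is
  converted to the active thiol metabolite, which is tracked only as a
  cumulative mass sink (its disposition is out of scope).
* **Parent disposition.**  One compartment (`V_cP`).  Systemic parent drug
  returns to the liver at clearance `CL_P`, where it faces the same
  fractional split, so every parent molecule is ultimately metabolised.
  Because `F_P` is below 1%, the effective first-pass extraction exceeds
  99% and the terminal parent slope is within 2% of `CL_P/V_cP`
  (apparent half-life `ln2·V_cP/CL_P ≈ 1.69 h` with the default values);
  both the headline `ln2·V/CL` convention and the exact slowest eigenvalue
  are exposed (`apparent_half_life`, `terminal_half_life`).
* **Metabolite disposition.**  Two compartments (`V_c_iaM`, `V_p_iaM`,
  inter-compartmental clearance `Q_iaM`) with linear elimination `CL_iaM`.

The liver wiring deserves a note, because several superficially similar
semi-physiological wirings exist.  We route the *entire* liver outflow
through the fraction split rather than balancing an intrinsic clearance
against `Q_h` in the liver: with the default parameter values the
alternative wiring would cap the first-pass extraction at
`CL_P/(Q_h+CL_P) ≈ 64%`, give a terminal half-life near 5 h, and predict
parent exposures ~50-fold higher than the metabolite-to-parent ratio this
drug actually shows.  The splitter wiring reproduces the >90% first-pass
effect, the ~1.7 h half-life, single-digit ng/mL parent peaks next to
µg/mL metabolite peaks, and it renders `Q_h` and `V_h` practically
unidentifiable — consistent with fixing them at literature values.  A
consequence worth remembering: the ultimate fraction of the dose reaching
CLO-CA is `F_iaM/(1−F_P)` (≈87.9% rather than 87.27%), because the escaped
parent fraction recycles; the *reported* `F_iaM` is always the algebraic
quantity from the fraction equations below.

**Dose fractions.**  `F_iaM`, `F_aM` and `F_P` follow a logit-style
parameterisation: `F_iaM = FR1/(1+FR1+FR2)`, `F_aM = FR2/(1+FR1+FR2)`,
`F_P = 1/(1+FR1+FR2)`.  `F_aM` is fixed at 12%, so `FR2` is solved from
`FR2 = F_aM(1+FR1)/(1−F_aM)` and only `FR1` (study-specific) is estimated.

**Covariates.**  Allometric body-weight scaling: exponent 0.75 on all
clearances (`CL_P`, `CL_iaM`, `Q_iaM`), 1 on all volumes (`V_cP`,
`V_c_iaM`, `V_p_iaM`, `V_h`), referenced to 70 kg.  `Q_h` is a fixed
physiological flow and is deliberately not scaled (it is listed without a
per-70-kg unit); this is configurable in code.

**Units.**  Amounts are carried in mg; parent concentrations are reported
in ng/mL (`A/V_cP` in mg/L × 1000) and metabolite concentrations in µg/mL
(`A/V_c_iaM` in mg/L), matching the assays' LLOQs of 0.5 ng/mL and
0.1 µg/mL.

## Solution methods

Three interchangeable prediction engines (`predict_concentrations`):

* `matrix_exp` (default): piecewise propagation with `scipy.linalg.expm`
  over the full 11-state system, including the cumulative sinks used by the
  mass-balance checks.
* `ode`: LSODA with `rtol 1e-12 / atol 1e-16`, retained as an independent
  cross-validation oracle; it agrees with the matrix exponential to better
  than 1e-6 relative even at vanishing late-time concentrations.
* `analytic`: closed-form inverse Laplace transform by partial fractions
  (a triple pole at `−K_tr` plus two parent and two metabolite disposition
  poles, all real and negative).  This path is vectorised over a batch of
  parameter sets and powers the mixed-effects machinery, where
  finite-difference stencils over random effects and population parameters
  are evaluated in single batched calls.  Nearly coincident poles (possible
  in the tails of the random-effect distributions) are nudged apart by a
  relative 1e-7; the induced error is far below the residual error and the
  default-parameter agreement with `matrix_exp` is ~1e-13.

## Statistical model and estimation

Random effects are log-normal: IIV on `V_cP`, `V_c_iaM`, `FR1` and
bioavailability `F` (the latter two with study-specific SDs), IOV on `F`
and `MTT` per crossover occasion — eight diagonal effects per subject.
Residual error is proportional with a study-specific SD applied to both
analytes.  Reported CV% uses the `100·sd` convention; the exact lognormal
transform is available.  Bioavailability is 1 (fixed) for the reference
formulation times a study-specific relative bioavailability `F_gen` for
the generic one.

The marginal likelihood integrates each subject's eight random effects by
the **Laplace approximation at the empirical-Bayes mode**: the mode is
found by BFGS with batched central-difference gradients, the eta Hessian is
an exact central finite-difference stencil (step 1e-3), and all 2π
constants are included, so `OFV = −2 log L` is comparable across nested
models and `AIC = OFV + 2p`, `BIC = OFV + p·ln(n_obs)`.  When all
random-effect SDs are zero the OFV reduces exactly to the pooled −2
log-likelihood.

Two implementation choices matter for anyone modifying the optimiser:

* **Variant re-centring.**  Objective gradients, covariance stencils and
  SIR proposals evaluate the OFV at many perturbed population vectors.  The
  eta mode moves with the population parameters, and the movement of the
  log-determinant term with the mode is *not* negligible (envelope
  arguments cover only the penalised-likelihood term).  Each perturbed
  variant therefore takes a Newton step in eta-space (using the cached
  base-mode Hessian) before the Laplace pieces are assembled, plus a
  second-order `−½∇gᵀH⁻¹∇g` correction for any residual offset.  Frozen
  modes without this correction misestimate absorption-parameter gradients
  several-fold.
* **Scaling.**  Free parameters are log-transformed by default; a native
  scale (linearly normalised by the initial value) is available and reaches
  the same optimum, which is one of the test-suite invariants.

Outer minimisation is L-BFGS-B with batched forward-difference gradients
(relative step 1e-4; a central option exists for near-interpolating
problems where forward truncation bias is material).  Standard errors come
from the inverse central-difference OFV Hessian (relative step 1e-4),
`Cov = 2·H⁻¹`, delta-method-transformed back to the natural scale.
Multi-start is available (`n_starts`, jittering initial values ±20%);
the default is a single start from the supplied initial values, which
profiling showed to be sufficient on this unimodal-in-practice problem —
the restart machinery is there for unusual datasets.

## Synthetic data

Because the underlying bioequivalence datasets are not public, the package
generates fully synthetic equivalents that carry the statistical structure
the analysis assumes: two independent 2×2 crossover studies (24 and 26
healthy subjects; single 150 mg doses; 14 samples/period to 48 h and 17
samples/period to 36 h), body weight ~ Normal(74.1, 13.56²) truncated to
[47, 100] kg, the IIV/IOV/error magnitudes above, and LLOQ censoring with
the M1 exclusion rule (values strictly below the LLOQ are dropped; equality
is retained; negative simulated values are likewise flagged).  Nominal
sampling times are not part of the public record; the defaults are
front-loaded grids consistent with rich absorption-phase sampling and are
configurable.  Washout between periods is assumed complete (half-life
~1.7 h versus ≥7-day washouts typical of such designs), so occasions are
simulated independently.

What the generator does *not* emulate: dropout, missed or delayed doses,
food effects, assay batch effects, model misspecification of any kind, and
pharmacogenetic covariates (CYP2C19/CES1).  Passing recovery tests on these
data therefore demonstrates internal consistency of the estimation
machinery under the assumed model, not robustness to real-data pathologies.
One real-data pathology *is* reproduced: the M1 exclusion of ~30–45% of
parent observations truncates the lower tail of the parent concentration
distribution, which visibly inflates parent volume/clearance-related
estimates in small samples — a known property of the exclusion rule, shared
with any analysis that discards censored records rather than integrating
them.

## Model evaluation

* **CWRES** — first-order linearisation around the EBEs:
  `CWRES = Cov^(−1/2)(y − f(θ,η̂) + Gη̂)` with `Cov = GΩGᵀ + diag((σf̂)²)`
  and the matrix square root by eigendecomposition.  Under the generating
  model the pooled residuals are approximately standard normal, which the
  tests check by moments and Kolmogorov–Smirnov.
* **VPC** — replicates of the original design (same subjects, weights,
  formulations, doses, nominal times) simulated under the fitted values,
  with the analysis LLOQ rule applied inside the simulation; binned 5th /
  50th / 95th percentiles with across-replicate 95% bands.  Bins are
  nominal times; sparse bins (fewer than 3 retained observations) merge
  leftward with a warning.  Prediction correction is not applied — the two
  formulations are handled by simulating the actual crossover design.
  The default is 1000 replicates.
* **SIR** — single-iteration sampling importance resampling: multivariate
  normal proposals at the estimates with covariance inflated ×1.5 on the
  transformed scale (defaults M = 5000 proposals, m = 1000 resamples
  without replacement), importance weights `∝ exp(−ΔOFV/2)/q`, with the
  effective sample size reported and a warning below `0.1·m`.  On
  quadratic (linear-Gaussian) OFV surfaces the resampled percentiles
  reproduce the analytic normal intervals, which is the calibration test.

## Numerical choices and degenerate inputs

* Fraction algebra is exact and validated to 1e-12 normalisation over 10⁴
  random draws; domain violations (non-positive `FR1`, `F_aM` outside
  (0,1), non-positive clearances/volumes, unsorted times, unknown methods
  or policies) raise `ValueError` eagerly.
* Random-effect dimensions whose SD is zero are excluded from mode search,
  prior, and determinant — the Laplace integral degrades gracefully to the
  pooled likelihood.
* Singular or indefinite eta Hessians and CWRES covariances are
  ridge-regularised with a warning; non-positive-definite proposal
  covariances in SIR are repaired by eigenvalue flooring.
* LLOQ boundary convention: strictly below is excluded, equality retained.
* Mass balance closes to 1e-8 (relative to dose) at all times, including
  the molecular-weight conversion of the metabolite path; the
  "other-elimination" state slot exists for alternative liver wirings and
  is identically zero here.

## Problem sizes used in the automated checks

The test suite exercises the full study design (24 + 26 subjects) wherever
a fit is not required (design bookkeeping, censoring patterns, CWRES
calibration, VPC self-calibration).  Estimation-heavy checks use reduced
but structurally complete problems, chosen as the smallest sizes at which
the checks remain informative: pooled (variability-free) fits use 3
subjects per study; the replicated simulate–refit study uses 6 subjects
per study, 20 replicates, a single jittered start and a 35-iteration cap
(estimates of the well-identified parameters are stationary well before
the cap; the cap mainly truncates the slowly-moving variance components).
The VPC self-calibration check uses 400 replicates rather than the
plotting default of 1000.

## Known limitations

* The active thiol metabolite is a mass sink; its plasma kinetics and
  CYP-mediated formation covariates are out of scope.
* No saturable metabolism, enterohepatic recirculation, or covariate
  search; weight enters only through fixed allometric exponents.
* BLQ records are excluded (M1), not integrated (M3); with ~30–45% of
  parent samples censored this induces the tail-truncation bias discussed
  above, in the package as in the original analysis convention.
* The SIR proposal is a single iteration; heavy-tailed or strongly
  correlated posteriors would need iterated proposals.
* Standard errors and SIR weights evaluate the OFV with eta modes
  re-centred by a single Newton pass rather than fully re-optimised;
  the agreement is second-order but not exact.
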