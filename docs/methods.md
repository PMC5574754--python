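# Methods

## Model

A prey library supplies mean signatures x̄_i (i = 1…I prey types) over
K fatty-acid slots; a predator sample supplies signatures y_j
(j = 1…J).  All signatures are compositions: strictly positive,
summing to one.  Calibration coefficients c_k map the prey
compositional space to the predator space,

    x̄ᵗ_ik = c_k x̄_ik / Σ_m c_m x̄_im,

and each predator signature is modelled as the diet-weighted mixture
ŷ_jk = Σ_i π_ji x̄ᵗ_ik.  The fit criterion is the squared Aitchison
distance between observed and modelled signatures summed over
predators,

    Q(π, c) = Σ_j Σ_k [ log(ŷ_jk / gm(ŷ_j)) − log(y_jk / gm(y_j)) ]²,

i.e. the squared Euclidean distance between centred log-ratio (clr)
transforms.  Constraints: π_ji ≥ 0, Σ_i π_ji = 1 per predator;
c_k ≥ 0.02 (bounding the coefficients away from zero, where log-ratio
quantities degenerate) and Σ_k c_k = K.  The sum constraint is pure
normalisation: the prey→predator mapping, and hence Q, is invariant to
rescaling c, so only K−1 coefficients are free.  Likewise Q is
invariant to rescaling any diet row (clr removes overall scale), so
only I−1 diet proportions per predator are free.

**Estimability.**  The predator data carry J(K−1) degrees of freedom
against J(I−1) + (K−1) parameters; all parameters are estimable only
when J ≥ (K−1)/(K−I) (requiring K > I).  `min_predators` returns the
ceiling of that ratio, and `fit_joint` refuses smaller samples: with a
single predator, diets and coefficients enter only through their
product and are completely confounded.  The threshold really applies
to the number of *distinct* diets: a sample of identical signatures
has effective size one regardless of J.  `fit_joint` therefore
supports multiple randomised feasible starts (`n_starts`); if two
starts reach the same objective (within 1e−10) at parameter estimates
differing by more than 1e−4 it raises an `IdentifiabilityWarning`
rather than silently picking one solution.

**Assumptions.**  The coefficients are common to all predators (if
sex, age or season are suspected to matter, partition the sample and
fit each subset); the library contains every prey type actually
consumed; prey types are characterised by their mean signatures
(within-type sampling variability is not propagated).

## Preprocessing

Raw signatures arrive as the dietary fatty-acid subset (K−1 named
columns).  Pipeline, in order: (1) zeros and missing values are
replaced by a small constant (default 0.005, configurable) so
logarithms are defined; (2) an augmentation component equal to one
minus the *pre-replacement* subset sum is appended, so the replacement
step does not inflate the measured mass (if the subset already sums to
one, the component is set to the replacement constant); (3) the full
K-vector is reclosed to sum exactly one.  The augmentation slot is an
ordinary component afterwards: it enters the geometric mean, the clr
transform and all distances.  Input sums are accepted to 1e−6
(CSV-rounding slack); closed vectors are validated to 1e−9.

Per-type mean signatures are the arithmetic mean of the preprocessed
specimen signatures, reclosed — the original QFASA convention.

## Optimisation

Two stages, both using analytic derivatives of Q.

1. **Block-coordinate stage.**  Starting from the conventional initial
   point (π_ji = 1/I, c_k = 1), alternate (a) each predator's diet
   given c — I-variable SLSQP problems with the simplex constraint —
   and (b) c given all diets — one K-variable SLSQP problem with the
   sum constraint and bounds.  Sweeps stop when the relative objective
   improvement falls below 5% (default cap 12 sweeps); the stage
   exists to place the iterate in the right basin and to identify most
   of the active set (true grid diets contain many exact zeros)
   cheaply.

2. **Active-set Levenberg–Marquardt polish.**  Q is a sum of squares
   of the clr residuals r_jk, whose Jacobian is block-angular: the
   residuals of predator j depend only on π_j and on c.  The damped
   Gauss–Newton normal equations are solved exactly by eliminating
   each (I_free−1)-sized diet block (Cholesky) and forming a Schur
   complement on the (K_free−1)-sized coefficient block, so one
   iteration costs O(J·K²·I) — seconds even at J = 210, I = 28,
   K = 42.  The scale directions (per-row diet scale, overall c scale)
   are removed from each block with an orthonormal zero-sum (Helmert)
   basis, which keeps the damped system well posed; variables at their
   bounds are fixed, with a Lagrange-multiplier test (reduced gradient
   against the mean over free components) releasing them when a
   descent direction into the feasible region exists.  Trial points
   are projected — diet entries clipped at zero and rows renormalised,
   coefficients clipped at the lower bound — which is cost-free
   because Q is invariant to those scales.  Damping: λ scaled by the
   mean block-diagonal magnitude, ×0.25 on acceptance, ×10 on
   rejection, stall declared above 1e12.

   Near a zero-residual solution the Gauss–Newton step converges
   quadratically, driving Q to the order of squared machine rounding
   (~1e−27 in the validation experiments) and the parameter errors to
   ~1e−15.  Defaults: stop when Q < 1e−26 (`q_tol`) or when five
   consecutive accepted steps improve Q by less than one part in 1e9;
   convergence is declared when Q ≤ 1e−18 or the projected KKT
   residual is below `opt_tol` (1e−8), otherwise the result is flagged
   (never silently returned) with its status and KKT residual.

   At the solution the constraints are restored exactly (rows
   renormalised, c rescaled to sum K) — again free, by scale
   invariance.

**Conditioned mode** (classical QFASA) fixes c and estimates each diet
independently — the objective separates over predators — using the
same SLSQP + single-block polish machinery.

**Degenerate inputs.**  K ≤ I and J below the estimability threshold
raise; all-zero signatures raise; identical predators converge (the
exact-fit manifold is a continuum) but trigger the multistart warning
above.  Near-threshold samples (J barely above the minimum, diets of
low diversity) are a documented hard regime: the fit completes and
reports its status honestly, and small residual objectives there are
expected rather than treated as failures.

## Synthetic-data generator

The generator produces all validation inputs with known truth:

* **Diet grids** (`make_diet_grid`): all I-part compositions with
  components on a regular increment 1/g, enumerated lexicographically
  as integer unit counts (exact in rational arithmetic; C(I+g−1, g)
  diets), converted to proportions only on output.  Increment 0.25
  gives 210 diets at I=7 and 31,465 at I=28; the fish-dimension
  experiment subsamples 210 of those uniformly without replacement
  under the scenario seed.
* **Calibration coefficients** (`random_cc`): χ²(1) draws scaled to
  sum K.  Raw draws below the 0.02 bound are redrawn before scaling
  (and the scale-then-check loop repeats) so the simulated truth is
  interior to the estimator's feasible region — otherwise recovery
  error would be bounded away from zero by construction.
* **Prey libraries** (`synth_prey_library`): logistic-normal.  Type
  mean log-profiles are a shared standard-normal baseline plus a
  type-specific standard-normal offset scaled by `separation`
  (default 1.0, giving clearly distinct types; 0 collapses all types —
  the degenerate control); specimens scatter around their type mean
  with log-scale standard deviation `within_sd` (default 0.25, a
  moderate within-type heterogeneity).  Defaults emulate the
  dimensional structure of real marine libraries (I prey types, K
  slots including augmentation, n specimens per type), *not* the
  fatty-acid values of any real library.
* **Predators** (`generate_predators`): noise-free.  The default
  construction mixes the *transformed* prey means in the predator
  space, y_j = Σ_i π_ji · closure(c∘x̄_i) — the exact generative
  counterpart of the estimation model, so the true (π, c) is the
  unique exact fit when the diets span the simplex, and recovery
  experiments measure solver accuracy alone.  The alternative
  `mixing="prey"` mixes raw means in the prey space and then
  transforms, y_j = closure(c ∘ Σ_i π_ji x̄_i), the construction used
  by prey-space formulations of QFASA.  The two differ whenever the
  coefficient-weighted masses s_i = Σ_k c_k x̄_ik vary across prey
  types: the prey-space construction equals the predator-space model
  evaluated at the reweighted diet π′_i ∝ π_i s_i, so an exact fit of
  such data recovers π′, not π.  Because the package's validation
  contract is exact recovery of the generating parameters, the
  self-consistent predator-space construction is the default; both
  are unit-tested against independent two-step oracles.
* **Realistic diets** (`realistic_diet_fixture`): four packaged
  low-diversity diets per library dimension (one or two dominant prey
  types, several near-zero contributions), synthetic stand-ins shaped
  like published polar-bear and gray-seal diet profiles.  They drive
  the near-threshold J=4 test cases.

All randomness flows through a single seeded `numpy` generator
recorded in the scenario.

**What passing tests do and do not show.**  The validation is
noise-free by design: it demonstrates that the joint model is
identifiable at these dimensions and that the solver recovers the
exact optimum, which is the model's self-consistency claim.  It does
not quantify performance under signature measurement noise,
within-prey-type variability, library misspecification (missing prey
types), or violations of the common-coefficient assumption; real-data
estimates inherit all of those.

## Problem sizes and tolerances in the shipped tests

The test suite exercises recovery at the two real-library
dimensionalities — I=7/K=32 with all 210 gridded diets and I=28/K=42
with 210 diets sampled from the full grid (30 specimens per type,
separation 1.0) — asserting Q < 1e−18 and parameter errors < 1e−10,
plus the J=4 near-threshold cases and a conditioning-bias contrast
(data generated with random coefficients, fit conditioned on c=1:
diet errors above 0.01; joint fit: below 1e−8).  Smaller I=3/K=8
scenarios back the unit and property tests.

## Known limitations

* No uncertainty quantification for individual diet estimates; only
  per-class means with the standard error of the mean
  (`summarize_by_class`).  No covariance of (π̂, ĉ) is produced.
* Estimation is performed in the predator space; prey-space
  *estimation* is not offered (the prey-space transform is available
  as a utility, and prey-space *generation* as `mixing="prey"`).
* Calibration coefficients are global to the fitted sample; model
  heterogeneity by partitioning the data, not within the model.
* The χ²(1) coefficient simulation and the logistic-normal library
  generator are conventional choices, not fitted to any organism.
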