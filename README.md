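# qfasajoint

Joint estimation of predator diet composition and fatty-acid
calibration coefficients from signature data.

## The problem

Quantitative fatty acid signature analysis (QFASA) estimates what a
predator has been eating from the fatty-acid composition of its fat
tissue.  The fundamental data unit is a *signature*: a vector of
proportions over K fatty-acid slots summing to one.  A predator
signature is modelled as a mixture of the mean signatures of its
potential prey types, after adjusting each fatty acid by a
*calibration coefficient* c_k that accounts for differential
metabolism.  Classical QFASA must **condition** on calibration
coefficients measured in captive feeding trials with surrogate
species — an unverifiable assumption, and a biased one whenever the
trial coefficients do not transfer to the wild predator.

`qfasajoint` implements the joint model in which the diet proportions
π_ji of every predator *and* the shared calibration coefficients c_k
are estimated **simultaneously** from the predator and prey signature
samples alone, by minimising the summed squared Aitchison distance

    Q = Σ_j Σ_k [ log(ŷ_jk / gm(ŷ_j)) − log(y_jk / gm(y_j)) ]²,

where ŷ_jk = Σ_i π_ji x̄ᵗ_ik mixes the prey mean signatures
transformed into the predator space, x̄ᵗ_ik = c_k x̄_ik / Σ_m c_m x̄_im,
and gm(·) is the geometric mean.  Constraints: each diet row is
non-negative and sums to one; the coefficients satisfy c_k ≥ 0.02 and
Σ c_k = K (coefficients are identifiable only up to scale).  The data
carry J(K−1) degrees of freedom against J(I−1) + (K−1) parameters, so
estimation requires J ≥ (K−1)/(K−I) predators with *distinct* diets.

The package also ships the full validation machinery: regular diet
grids over the simplex, random calibration coefficients (χ²(1) draws
scaled to sum K), synthetic prey libraries with controllable
between-type separation, noise-free predator generation, the classical
conditioned estimator for comparison, and per-class diet summaries.

It is aimed at quantitative ecologists working with fatty-acid
signature data (marine mammal and fish diet studies in particular) and
at methodologists studying compositional mixture models.

## Worked example

Recover known diets and coefficients from noise-free synthetic data at
marine-mammal library dimensions (7 prey types, 32 signature
proportions, all 210 diets of a 0.25-increment grid):

```python
import numpy as np
from qfasajoint import (fit_joint, fit_conditioned, generate_predators,
                        make_diet_grid, random_cc, synth_prey_library,
                        CalibrationCoefficients)

library = synth_prey_library(I=7, K=32, n_per_type=30, separation=1.0, seed=0)
cc_true = random_cc(32, seed=1)
diets_true = make_diet_grid(7, 0.25)            # 210 diets
predators = generate_predators(diets_true, library, cc_true)

result = fit_joint(predators, library)
print(f"Q at solution:        {result.objective:.3e}")
print(f"max |diet error|:     {np.abs(result.diet.values - diets_true).max():.3e}")
print(f"max |cc error|:       {np.abs(result.cc.values - cc_true.values).max():.3e}")

biased = fit_conditioned(predators, library, CalibrationCoefficients.ones(32))
print(f"conditioned on c=1, max |diet error|: "
      f"{np.abs(biased.diet.values - diets_true).max():.3f}")
```

prints

```
Q at solution:        1.176e-27
max |diet error|:     2.220e-16
max |cc error|:       8.882e-16
conditioned on c=1, max |diet error|: 0.552
```

The joint fit drives the objective to numerical zero and recovers both
parameter blocks to machine precision, while the classical estimator
conditioned on wrong (identity) coefficients misestimates diet
proportions by up to 0.55 on the same data — the bias the joint model
exists to remove.

The same workflow is available from the shell:

```sh
qfasajoint simulate --prey-types 7 --fatty-acids 32 --seed 0 --out-dir sim/
qfasajoint fit --prey sim/prey.csv --predators sim/predators.csv \
    --mode joint --true-diets sim/true_diets.csv --true-cc sim/true_cc.csv \
    --out-dir fit/
qfasajoint evaluate --est-diets fit/diets.csv --true-diets sim/true_diets.csv \
    --out-dir eval/
```

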