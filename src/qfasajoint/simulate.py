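"""Simulation machinery for validating the joint model with known truth.

Everything needed to reproduce the validation design: regular diet
grids over the simplex, random calibration coefficients drawn from a
chi-square(1) density and scaled to sum ``K``, synthetic prey libraries
with controllable between-type separation, and noise-free predator
signatures generated from known diets and coefficients.

The synthetic prey library stands in for real signature libraries
(which are not redistributable): it emulates their dimensional
structure — ``I`` prey types, ``K`` fatty-acid slots including the
augmentation component, ``n`` specimens per type — via a
logistic-normal generator, not their actual fatty-acid values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signatures import PredatorSample, PreyLibrary, closure
from .transform import (
    DEFAULT_CC_LOWER_BOUND,
    CalibrationCoefficients,
    DietMatrix,
    to_predator_space,
)

__all__ = [
    "SimulationScenario",
    "SimulationResult",
    "make_diet_grid",
    "random_cc",
    "synth_prey_library",
    "generate_predators",
    "realistic_diet_fixture",
    "run_scenario",
]


def _grid_counts(total: int, parts: int):
    """Lexicographic integer compositions of ``total`` into ``parts``."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _grid_counts(total - first, parts - 1):
            yield (first,) + rest


def make_diet_grid(I: int, increment: float, return_counts: bool = False) -> np.ndarray:
    """All diet vectors with components on a regular grid of the simplex.

    Components are multiples of ``increment`` summing exactly to one;
    with ``g = 1/increment`` the grid holds ``C(I+g-1, g)`` diets.
    Enumeration is lexicographic and performed on integer unit counts
    (returned directly with ``return_counts=True``), so the grid is
    exact in rational arithmetic; proportions are formed only on output.
    """
    I = int(I)
    if I < 2:
        raise ValueError("a diet grid needs at least two prey types")
    g = round(1.0 / increment)
    if g < 1 or abs(1.0 / increment - g) > 1e-9:
        raise ValueError("1/increment must be a positive integer")
    counts = np.array(list(_grid_counts(g, I)), dtype=np.int64)
    if return_counts:
        return counts
    return counts / float(g)


def random_cc(
    K: int,
    seed=None,
    lower_bound: float = DEFAULT_CC_LOWER_BOUND,
) -> CalibrationCoefficients:
    """Random calibration coefficients: chi-square(1) draws scaled to sum K.

    Raw draws below ``lower_bound`` are redrawn before scaling, and the
    scale-then-check loop repeats until the scaled vector also clears
    the bound, so simulated truth always lies in the interior of the
    feasible region of the estimator.  ``seed`` may be an integer or a
    :class:`numpy.random.Generator`.
    """
    K = int(K)
    if K < 2:
        raise ValueError("need at least two fatty acids")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(1000):
        draws = rng.chisquare(1.0, K)
        for _ in range(1000):
            low = draws < lower_bound
            if not low.any():
                break
            draws[low] = rng.chisquare(1.0, int(low.sum()))
        scaled = draws * (K / draws.sum())
        if scaled.min() >= lower_bound:
            return CalibrationCoefficients(scaled, lower_bound=lower_bound)
    raise RuntimeError("failed to draw feasible calibration coefficients")


def synth_prey_library(
    I: int,
    K: int,
    n_per_type: int,
    separation: float = 1.0,
    seed=None,
    within_sd: float = 0.25,
) -> PreyLibrary:
    """Synthetic prey library with controllable between-type separation.

    Type mean compositions are logistic-normal: a common baseline
    log-profile plus a type-specific normal offset scaled by
    ``separation`` (``separation=0`` collapses all type means onto the
    baseline — the worst case for diet estimation).  Specimens scatter
    around their type mean by a logistic-normal perturbation of
    standard deviation ``within_sd`` on the log scale.
    """
    I, K, n_per_type = int(I), int(K), int(n_per_type)
    if K <= I:
        raise ValueError("need more fatty acids than prey types (K > I)")
    if n_per_type < 1:
        raise ValueError("need at least one specimen per type")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    baseline = rng.normal(0.0, 1.0, size=K)
    offsets = rng.normal(0.0, 1.0, size=(I, K))
    type_logits = baseline + separation * offsets
    rows, types = [], []
    for i in range(I):
        eps = rng.normal(0.0, 1.0, size=(n_per_type, K))
        rows.append(closure(np.exp(type_logits[i] + within_sd * eps)))
        types.extend([f"type_{i + 1}"] * n_per_type)
    labels = tuple(f"fa_{k + 1}" for k in range(K - 1)) + ("aug",)
    return PreyLibrary.from_matrix(np.vstack(rows), types, labels)


def generate_predators(
    diets,
    library: PreyLibrary,
    cc,
    mixing: str = "predator",
    ids=None,
    classes=None,
) -> PredatorSample:
    """Noise-free predator signatures from known diets and coefficients.

    ``mixing="predator"`` (default) mixes the *transformed* prey means
    in the predator space, ``y_j = sum_i pi[j,i] * closure(c * xbar_i)``
    — the exact generative counterpart of the estimation model, so a
    joint fit of the output can recover the generating diets and
    coefficients with essentially no error.  ``mixing="prey"`` mixes
    the raw means in the prey space first and then transforms,
    ``y_j = closure(c * sum_i pi[j,i] * xbar_i)``; the two constructions
    coincide only when all prey rows share the same coefficient-weighted
    mass ``s_i = sum_k c_k xbar[i,k]``.  Both are invariant to rescaling
    ``cc``.
    """
    pi = diets.values if isinstance(diets, DietMatrix) else np.asarray(diets, float)
    if pi.ndim != 2 or pi.shape[1] != library.n_types:
        raise ValueError("diet columns must match the library's prey types")
    if np.any(pi < -1e-12) or np.any(np.abs(pi.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("each diet must be proportions summing to 1")
    c = cc.values if isinstance(cc, CalibrationCoefficients) else np.asarray(cc, float)
    xbar = library.mean_signatures
    if mixing == "predator":
        Y = closure(pi @ to_predator_space(xbar, c))
    elif mixing == "prey":
        Y = closure((pi @ xbar) * c)
    else:
        raise ValueError("mixing must be 'predator' or 'prey'")
    J = Y.shape[0]
    if ids is None:
        ids = tuple(f"pred_{j + 1}" for j in range(J))
    return PredatorSample(Y, ids, library.labels, classes)


# Packaged low-diversity test diets: synthetic stand-ins shaped like
# published predator diets (one or two dominant prey types, several
# near-zero contributions), NOT reproductions of any published values.
_REALISTIC_MAMMAL = {
    "adult_female": [0.05, 0.25, 0.02, 0.01, 0.57, 0.05, 0.05],
    "adult_male": [0.04, 0.38, 0.02, 0.01, 0.45, 0.03, 0.07],
    "subadult_female": [0.02, 0.12, 0.01, 0.04, 0.70, 0.09, 0.02],
    "subadult_male": [0.03, 0.15, 0.02, 0.04, 0.66, 0.07, 0.03],
}
_REALISTIC_FISH_SPARSE = {
    "spring_female": {0: 0.54, 4: 0.20, 7: 0.10, 12: 0.05, 18: 0.05, 22: 0.05, 26: 0.01},
    "spring_male": {0: 0.44, 4: 0.25, 7: 0.12, 10: 0.08, 18: 0.05, 25: 0.05, 26: 0.01},
    "fall_female": {0: 0.30, 4: 0.34, 7: 0.15, 12: 0.08, 15: 0.07, 22: 0.05, 27: 0.01},
    "fall_male": {0: 0.25, 4: 0.39, 7: 0.10, 10: 0.10, 15: 0.10, 25: 0.05, 27: 0.01},
}


def realistic_diet_fixture(case: str) -> DietMatrix:
    """Four packaged low-diversity diets for near-threshold test cases.

    ``case="mammal"`` returns 4 diets over 7 prey types (polar-bear-like
    age–sex classes), ``case="fish"`` 4 diets over 28 prey types
    (gray-seal-like season–sex classes).  The values are synthetic
    fixture data shipped with the package.
    """
    if case == "mammal":
        rows = np.array(list(_REALISTIC_MAMMAL.values()), dtype=float)
        ids = tuple(_REALISTIC_MAMMAL)
        I = 7
    elif case == "fish":
        I = 28
        rows = np.zeros((4, I))
        for r, sparse in enumerate(_REALISTIC_FISH_SPARSE.values()):
            for i, v in sparse.items():
                rows[r, i] = v
        ids = tuple(_REALISTIC_FISH_SPARSE)
    else:
        raise ValueError("case must be 'mammal' or 'fish'")
    return DietMatrix(rows, predator_ids=ids)


@dataclass(frozen=True)
class SimulationScenario:
    """Generative settings for one validation experiment.

    Diets come from a regular grid (``increment``), optionally
    subsampled to ``n_predators`` without replacement, or from an
    explicit ``diets`` array.  Coefficients come from the seeded
    chi-square(1) draw unless ``cc`` is given.  The prey library is the
    synthetic generator unless ``mean_signatures`` is given.
    """

    n_prey_types: int
    n_fatty_acids: int
    increment: float = 0.25
    n_predators: int | None = None
    diets: np.ndarray | None = None
    cc: np.ndarray | None = None
    n_per_type: int = 30
    separation: float = 1.0
    within_sd: float = 0.25
    mixing: str = "predator"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fatty_acids <= self.n_prey_types:
            raise ValueError("need more fatty acids than prey types (K > I)")
        g = round(1.0 / self.increment)
        if g < 1 or abs(1.0 / self.increment - g) > 1e-9:
            raise ValueError("1/increment must be a positive integer")


@dataclass(frozen=True)
class SimulationResult:
    library: PreyLibrary
    predators: PredatorSample
    true_diets: DietMatrix
    true_cc: CalibrationCoefficients


def run_scenario(scenario: SimulationScenario) -> SimulationResult:
    """Generate the full set of inputs for one validation experiment.

    All randomness (library, coefficient draw, grid subsampling) flows
    through a single generator seeded with ``scenario.seed``.
    """
    rng = np.random.default_rng(scenario.seed)
    library = synth_prey_library(
        scenario.n_prey_types,
        scenario.n_fatty_acids,
        scenario.n_per_type,
        separation=scenario.separation,
        seed=rng,
        within_sd=scenario.within_sd,
    )
    if scenario.cc is not None:
        cc = CalibrationCoefficients.from_raw(scenario.cc)
    else:
        cc = random_cc(scenario.n_fatty_acids, seed=rng)
    if scenario.diets is not None:
        diets = np.asarray(scenario.diets, dtype=float)
    else:
        diets = make_diet_grid(scenario.n_prey_types, scenario.increment)
        if scenario.n_predators is not None and scenario.n_predators < diets.shape[0]:
            pick = rng.choice(diets.shape[0], scenario.n_predators, replace=False)
            diets = diets[np.sort(pick)]
    predators = generate_predators(diets, library, cc, mixing=scenario.mixing)
    return SimulationResult(
        library=library,
        predators=predators,
        true_diets=DietMatrix(diets, library.prey_types, predators.ids),
        true_cc=cc,
    )
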