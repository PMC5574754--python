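"""Joint and conditioned estimation of diets and calibration coefficients.

The joint model treats both the diet proportions ``pi[j, i]`` of every
predator and the calibration coefficients ``c[k]`` (shared by all
predators) as unknowns, estimated by minimising the summed squared
Aitchison distance between observed and modelled predator signatures

    Q = sum_j sum_k [ log(yhat[j,k]/gm(yhat[j])) - log(y[j,k]/gm(y[j])) ]^2

subject to: each diet row non-negative and summing to one, coefficients
at least ``0.02`` and summing to ``K``.  The predator signature data
carry ``J*(K-1)`` degrees of freedom against ``J*(I-1) + (K-1)``
parameters, so all parameters are estimable only when
``J >= (K-1)/(K-I)`` (``K > I``) — and, in practice, only when the
sample contains that many *distinct* diets: with identical predator
signatures the effective sample size is one and diets and coefficients
are completely confounded.

Conditioned estimation is classical QFASA: the coefficients are fixed
to externally supplied values and each predator's diet is estimated
independently (the objective separates over predators).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _solver
from .signatures import PredatorSample, PreyLibrary, clr
from .transform import (
    DEFAULT_CC_LOWER_BOUND,
    CalibrationCoefficients,
    DietMatrix,
    to_predator_space,
)

__all__ = [
    "FitConfig",
    "JointFitResult",
    "ConditionedFitResult",
    "ClassDietSummary",
    "UnderdeterminedError",
    "IdentifiabilityWarning",
    "min_predators",
    "count_parameters",
    "objective_q",
    "fit_joint",
    "fit_conditioned",
    "summarize_by_class",
]


class UnderdeterminedError(ValueError):
    """The model has fewer degrees of freedom than parameters."""


class IdentifiabilityWarning(UserWarning):
    """Multiple starts reached the same objective at different parameters."""


def min_predators(K: int, I: int) -> int:
    """Smallest predator sample size at which all parameters are estimable.

    Equates the data degrees of freedom ``J*(K-1)`` with the parameter
    count ``J*(I-1) + (K-1)``: ``J >= (K-1)/(K-I)`` for ``K > I``.
    """
    K, I = int(K), int(I)
    if I < 2:
        raise ValueError("at least two prey types are required")
    if K <= I:
        raise UnderdeterminedError(
            "model underdetermined: need more fatty acids than prey types"
        )
    return -((K - 1) // -(K - I))


def count_parameters(J: int, I: int, K: int) -> int:
    """Number of free parameters: ``J*(I-1)`` diets plus ``K-1`` coefficients."""
    J, I, K = int(J), int(I), int(K)
    if min(J, I, K) < 1:
        raise ValueError("J, I and K must be positive")
    return J * (I - 1) + (K - 1)


@dataclass(frozen=True)
class FitConfig:
    """Optimisation settings for joint and conditioned fits.

    Defaults mirror the published set-up: diets start at ``1/I``,
    coefficients at 1, the coefficient sum is constrained to ``K`` and
    each coefficient bounded below by 0.02.  ``opt_tol`` is the
    first-order (projected KKT) tolerance used to declare convergence;
    ``q_tol`` is the objective level at which polishing stops (squared
    machine rounding — the objective cannot meaningfully go lower).
    """

    cc_lower_bound: float = DEFAULT_CC_LOWER_BOUND
    cc_sum: float | None = None          # default: K
    diet_init: str = "uniform"           # 1/I per component
    cc_init: str = "ones"
    opt_tol: float = 1e-8
    q_tol: float = 1e-26
    max_outer: int = 12                  # block-coordinate sweeps
    max_iter: int = 5000                 # total iteration budget
    polish: bool = True
    n_starts: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.opt_tol <= 0 or self.q_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.n_starts < 1:
            raise ValueError("n_starts must be at least 1")


@dataclass(frozen=True)
class JointFitResult:
    """Estimated diets and coefficients with convergence diagnostics."""

    diet: DietMatrix
    cc: CalibrationCoefficients
    objective: float
    converged: bool
    n_iterations: int
    kkt_residual: float
    status: str
    start_objectives: tuple[float, ...] = ()


@dataclass(frozen=True)
class ConditionedFitResult:
    """Per-predator diet estimates with coefficients held fixed."""

    diet: DietMatrix
    objectives: np.ndarray               # per-predator Aitchison term
    converged: bool

    @property
    def objective(self) -> float:
        return float(self.objectives.sum())


def _validate_inputs(predators: PredatorSample, library: PreyLibrary) -> None:
    if predators.labels != library.labels:
        raise ValueError(
            "predator and prey fatty-acid labels differ (order matters); "
            "align the two tables before fitting"
        )


def objective_q(diet, cc, predators: PredatorSample, mean_signatures) -> float:
    """Evaluate Q at given diets and coefficients (no optimisation)."""
    pi = diet.values if isinstance(diet, DietMatrix) else np.asarray(diet, float)
    c = cc.values if isinstance(cc, CalibrationCoefficients) else np.asarray(cc, float)
    xbar = np.asarray(mean_signatures, dtype=float)
    if np.any(c <= 0.0) or np.any(xbar <= 0.0):
        raise ValueError("coefficients and mean signatures must be positive")
    y = predators.signatures if isinstance(predators, PredatorSample) else np.asarray(predators, float)
    T = to_predator_space(xbar, c)
    yhat = pi @ T
    if np.any(yhat <= 0.0):
        raise ValueError("modelled proportions must be strictly positive")
    z = clr(y, axis=1)
    r = clr(yhat, axis=1) - z
    return float((r * r).sum())


def _block_coordinate(pi, c, xbar, z, lb, csum, max_outer):
    """SLSQP sweeps: diets given coefficients, coefficients given diets."""
    Q_prev = math.inf
    sweeps = 0
    for _ in range(max_outer):
        T, _ = _solver.transformed_means(xbar, c)
        for j in range(pi.shape[0]):
            pi[j] = _solver.fit_diet_slsqp(z[j], T, pi[j])[0]
        c, _ = _solver.fit_cc_slsqp(c, pi, xbar, z, lb, csum)
        Q = _solver.q_value(pi, c, xbar, z)
        sweeps += 1
        if Q < 1e-16 or Q > 0 and (Q_prev - Q) < 0.05 * max(Q_prev, 1e-300):
            break
        Q_prev = Q
    return pi, c, sweeps


def _fit_from_start(pi0, c0, xbar, z, lb, csum, config: FitConfig):
    pi, c, sweeps = _block_coordinate(
        pi0.copy(), c0.copy(), xbar, z, lb, csum, config.max_outer
    )
    if config.polish:
        res = _solver.lm_polish(
            pi, c, xbar, z,
            lb=lb, csum=csum,
            q_tol=config.q_tol,
            max_iter=max(config.max_iter - sweeps, 1),
        )
        pi, c, Q = res.pi, res.c, res.objective
        iters = sweeps + res.n_iterations
        kkt = res.kkt_residual
        status = res.status
    else:
        pi = pi / pi.sum(axis=1, keepdims=True)
        c = c * (csum / c.sum())
        Q = _solver.q_value(pi, c, xbar, z)
        kkt = _solver.kkt_residual(pi, c, xbar, z, lb, False)
        iters = sweeps
        status = "block-coordinate"
    return pi, c, Q, iters, kkt, status


def _random_start(rng, J, I, K, lb, csum):
    pi = rng.dirichlet(np.ones(I), size=J)
    e = rng.exponential(size=K)
    c = lb + e * (csum - K * lb) / e.sum()
    return pi, c


def fit_joint(
    predators: PredatorSample,
    library: PreyLibrary,
    config: FitConfig | None = None,
) -> JointFitResult:
    """Simultaneously estimate all diets and the calibration coefficients.

    Raises :class:`UnderdeterminedError` when the predator sample is
    smaller than ``min_predators(K, I)``.  With ``config.n_starts > 1``
    additional randomised feasible starts are run; if two starts reach
    the same objective (within 1e-10) at parameter estimates differing
    by more than 1e-4, an :class:`IdentifiabilityWarning` is raised —
    the hallmark of a confounded sample (e.g. identical predators).
    """
    config = config or FitConfig()
    _validate_inputs(predators, library)
    xbar = library.mean_signatures
    I, K = xbar.shape
    J = predators.n_predators
    j_min = min_predators(K, I)
    if J < j_min:
        raise UnderdeterminedError(
            f"joint estimation needs at least {j_min} predators for "
            f"K={K} fatty acids and I={I} prey types (got J={J}); with a "
            "single predator, diets and calibration coefficients are "
            "completely confounded"
        )
    lb = config.cc_lower_bound
    csum = float(K) if config.cc_sum is None else float(config.cc_sum)
    z = clr(predators.signatures, axis=1)

    rng = np.random.default_rng(config.seed)
    starts = [(np.full((J, I), 1.0 / I), np.full(K, csum / K))]
    for _ in range(config.n_starts - 1):
        starts.append(_random_start(rng, J, I, K, lb, csum))

    fits = [_fit_from_start(pi0, c0, xbar, z, lb, csum, config) for pi0, c0 in starts]
    objectives = tuple(f[2] for f in fits)
    best = int(np.argmin(objectives))
    pi, c, Q, iters, kkt, status = fits[best]

    for k, fit in enumerate(fits):
        if k == best:
            continue
        if abs(fit[2] - Q) <= 1e-10:
            dmax = max(
                float(np.abs(fit[0] - pi).max()), float(np.abs(fit[1] - c).max())
            )
            if dmax > 1e-4:
                warnings.warn(
                    "multiple starts reached the same objective at estimates "
                    f"differing by up to {dmax:.2e}; diets and calibration "
                    "coefficients appear confounded (insufficient diet "
                    "diversity in the predator sample)",
                    IdentifiabilityWarning,
                    stacklevel=2,
                )
                break

    converged = Q <= 1e-18 or kkt <= config.opt_tol
    if not converged:
        warnings.warn(
            f"joint fit did not meet the convergence criteria "
            f"(Q={Q:.3e}, KKT residual={kkt:.3e}); result flagged",
            UserWarning,
            stacklevel=2,
        )
    return JointFitResult(
        diet=DietMatrix(pi, library.prey_types, predators.ids),
        cc=CalibrationCoefficients(c, lower_bound=lb, sum_constraint=csum),
        objective=Q,
        converged=bool(converged),
        n_iterations=iters,
        kkt_residual=kkt,
        status=status,
        start_objectives=objectives,
    )


def fit_conditioned(
    predators: PredatorSample,
    library: PreyLibrary,
    cc_fixed,
    config: FitConfig | None = None,
) -> ConditionedFitResult:
    """Classical QFASA: per-predator diets with coefficients held fixed.

    Because the objective separates over predators once the
    coefficients are fixed, each diet is estimated independently.
    """
    config = config or FitConfig()
    _validate_inputs(predators, library)
    xbar = library.mean_signatures
    I, K = xbar.shape
    c = cc_fixed.values if isinstance(cc_fixed, CalibrationCoefficients) else np.asarray(cc_fixed, float)
    if c.size != K or np.any(c <= 0.0):
        raise ValueError("fixed calibration coefficients must be positive, length K")
    z = clr(predators.signatures, axis=1)
    T, _ = _solver.transformed_means(xbar, c)

    J = predators.n_predators
    pi = np.empty((J, I))
    objectives = np.empty(J)
    ok = True
    for j in range(J):
        pj, _ = _solver.fit_diet_slsqp(z[j], T, np.full(I, 1.0 / I))
        if config.polish:
            res = _solver.lm_polish(
                pj[None, :], c, xbar, z[j][None, :],
                lb=config.cc_lower_bound, csum=float(K), c_fixed=True,
                q_tol=config.q_tol, max_iter=200,
            )
            pj = res.pi[0]
            objectives[j] = res.objective
            ok = ok and res.status in ("converged", "stalled", "maxiter")
        else:
            objectives[j] = _solver.q_value(pj[None, :], c, xbar, z[j][None, :])
        pi[j] = pj
    return ConditionedFitResult(
        diet=DietMatrix(pi, library.prey_types, predators.ids),
        objectives=objectives,
        converged=ok,
    )


@dataclass(frozen=True)
class ClassDietSummary:
    """Per-class mean diet and standard error of the mean."""

    classes: tuple[str, ...]
    prey_types: tuple[str, ...] | None
    counts: np.ndarray                   # predators per class
    means: np.ndarray                    # C x I, rows sum to 1
    ses: np.ndarray                      # C x I, sd / sqrt(n); 0 when n == 1

    def to_frame(self) -> pd.DataFrame:
        cols = self.prey_types or tuple(
            f"prey_{i + 1}" for i in range(self.means.shape[1])
        )
        rows = []
        for ci, cl in enumerate(self.classes):
            for pi_, pt in enumerate(cols):
                rows.append(
                    {
                        "class": cl,
                        "prey_type": pt,
                        "n": int(self.counts[ci]),
                        "mean": self.means[ci, pi_],
                        "se": self.ses[ci, pi_],
                    }
                )
        return pd.DataFrame(rows)


def summarize_by_class(diet, classes) -> ClassDietSummary:
    """Mean diet and SE of the mean for each predator class.

    Predators with a missing class label are excluded with a warning;
    single-member classes report SE 0.
    """
    values = diet.values if isinstance(diet, DietMatrix) else np.asarray(diet, float)
    prey_types = diet.prey_types if isinstance(diet, DietMatrix) else None
    labels = list(classes)
    if len(labels) != values.shape[0]:
        raise ValueError("one class label per predator required")
    keep = [
        i for i, c in enumerate(labels)
        if c is not None and not (isinstance(c, float) and np.isnan(c))
    ]
    if len(keep) < len(labels):
        warnings.warn(
            f"excluding {len(labels) - len(keep)} predators without a class label",
            UserWarning,
            stacklevel=2,
        )
    if not keep:
        raise ValueError("no predators with class labels")
    values = values[keep]
    labels = [str(labels[i]) for i in keep]
    ordered = tuple(dict.fromkeys(labels))
    counts, means, ses = [], [], []
    for cl in ordered:
        rows = values[[l == cl for l in labels]]
        n = rows.shape[0]
        counts.append(n)
        means.append(rows.mean(axis=0))
        ses.append(
            rows.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.zeros(rows.shape[1])
        )
    return ClassDietSummary(
        classes=ordered,
        prey_types=prey_types,
        counts=np.asarray(counts),
        means=np.vstack(means),
        ses=np.vstack(ses),
    )
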