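"""Calibration-coefficient transforms between prey and predator space.

Calibration coefficients ``c_k`` account for the differential
metabolism of individual fatty acids: they provide a one-to-one mapping
between the compositional space of prey signatures and that of predator
signatures.  Mapping prey means into the predator space multiplies each
proportion by its coefficient and recloses,

    xbar_t[i, k] = c_k * xbar[i, k] / sum_m c_m * xbar[i, m],

and the inverse direction divides by the coefficients.  Only the
relative magnitudes of the coefficients matter (the mapping is invariant
to rescaling ``c``), so one identifiability constraint is imposed when
they are estimated: their sum equals the number of fatty acids ``K``.

Predator signatures are modelled as convex mixtures of the transformed
prey means weighted by diet proportions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .signatures import CLOSURE_ATOL, Signature, closure

__all__ = [
    "DEFAULT_CC_LOWER_BOUND",
    "CalibrationCoefficients",
    "DietMatrix",
    "to_predator_space",
    "to_prey_space",
    "predict_predator",
]

#: lower bound keeping estimated coefficients away from zero
DEFAULT_CC_LOWER_BOUND = 0.02


@dataclass(frozen=True)
class CalibrationCoefficients:
    """Vector of ``K`` positive multipliers under the sum-``K`` constraint.

    ``sum_constraint`` defaults to ``K`` (the identifiability convention
    used during estimation); ``lower_bound`` bounds the coefficients
    away from zero.
    """

    values: np.ndarray
    lower_bound: float = DEFAULT_CC_LOWER_BOUND
    sum_constraint: float | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("calibration coefficients must be a vector of length >= 2")
        target = float(vals.size) if self.sum_constraint is None else float(self.sum_constraint)
        object.__setattr__(self, "sum_constraint", target)
        if np.any(vals < self.lower_bound - 1e-9):
            raise ValueError("calibration coefficients below the lower bound")
        if abs(vals.sum() - target) > 1e-9 * max(1.0, target):
            raise ValueError("calibration coefficients violate the sum constraint")

    def __len__(self) -> int:
        return self.values.size

    @classmethod
    def ones(cls, K: int, lower_bound: float = DEFAULT_CC_LOWER_BOUND) -> "CalibrationCoefficients":
        """The identity mapping (all coefficients one); sums to ``K``."""
        return cls(np.ones(int(K)), lower_bound=lower_bound)

    @classmethod
    def from_raw(
        cls,
        values,
        lower_bound: float | None = None,
        sum_constraint: float | None = None,
    ) -> "CalibrationCoefficients":
        """Rescale arbitrary positive values to satisfy the sum constraint.

        With ``lower_bound=None`` the bound is relaxed to the smallest
        rescaled value if that falls below the default, so externally
        supplied coefficients (e.g. feeding-trial values) are accepted
        verbatim up to scale.
        """
        vals = np.asarray(values, dtype=float)
        if np.any(vals <= 0.0):
            raise ValueError("calibration coefficients must be strictly positive")
        target = float(vals.size) if sum_constraint is None else float(sum_constraint)
        scaled = vals * (target / vals.sum())
        if lower_bound is None:
            lower_bound = min(DEFAULT_CC_LOWER_BOUND, float(scaled.min()))
        return cls(scaled, lower_bound=lower_bound, sum_constraint=target)


@dataclass(frozen=True)
class DietMatrix:
    """J x I matrix of diet proportions, each row on the simplex."""

    values: np.ndarray
    prey_types: tuple[str, ...] | None = None
    predator_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError("diet matrix must be two-dimensional")
        if np.any(vals < -1e-12):
            raise ValueError("diet proportions must be non-negative")
        vals = np.clip(vals, 0.0, None)
        if np.any(np.abs(vals.sum(axis=1) - 1.0) > CLOSURE_ATOL):
            raise ValueError("each diet row must sum to 1")
        object.__setattr__(self, "values", vals)
        if self.prey_types is not None:
            object.__setattr__(self, "prey_types", tuple(self.prey_types))
            if len(self.prey_types) != vals.shape[1]:
                raise ValueError("one prey-type name per diet column required")
        if self.predator_ids is not None:
            object.__setattr__(self, "predator_ids", tuple(self.predator_ids))
            if len(self.predator_ids) != vals.shape[0]:
                raise ValueError("one predator id per diet row required")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _cc_array(cc) -> np.ndarray:
    vals = cc.values if isinstance(cc, CalibrationCoefficients) else np.asarray(cc, dtype=float)
    if np.any(vals <= 0.0):
        raise ValueError("calibration coefficients must be strictly positive")
    return vals


def to_predator_space(mean_signatures, cc) -> np.ndarray:
    """Map prey mean signatures into the predator space.

    Multiplies each row elementwise by the coefficients and recloses;
    the output rows sum to one.  Invariant to rescaling ``cc``.
    """
    X = np.asarray(mean_signatures, dtype=float)
    c = _cc_array(cc)
    if np.any(X <= 0.0):
        raise ValueError("mean signatures must be strictly positive")
    if X.shape[-1] != c.size:
        raise ValueError("signature length and coefficient length differ")
    return closure(X * c)


def to_prey_space(predator_signature, cc):
    """Map a predator signature back into the prey space (divide, reclose)."""
    c = _cc_array(cc)
    if isinstance(predator_signature, Signature):
        vals = closure(predator_signature.proportions / c)
        return Signature(vals, predator_signature.labels)
    x = np.asarray(predator_signature, dtype=float)
    if np.any(x <= 0.0):
        raise ValueError("predator signature must be strictly positive")
    if x.shape[-1] != c.size:
        raise ValueError("signature length and coefficient length differ")
    return closure(x / c)


def predict_predator(diet_row, transformed_means) -> np.ndarray:
    """Model a predator signature as a diet-weighted mixture.

    ``yhat_k = sum_i pi_i * xbar_t[i, k]`` — a convex combination of the
    transformed prey means, hence itself on the simplex.
    """
    pi = np.asarray(diet_row, dtype=float)
    T = np.asarray(transformed_means, dtype=float)
    if T.ndim != 2 or pi.ndim != 1 or pi.size != T.shape[0]:
        raise ValueError("diet length must match the number of prey types")
    if np.any(pi < -1e-12) or abs(pi.sum() - 1.0) > 1e-6:
        raise ValueError("diet row must be proportions summing to 1")
    return pi @ T
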