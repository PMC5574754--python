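"""Fit reports and evaluation against known simulation truth."""

from __future__ import annotations

import numpy as np

from .estimation import (
    ConditionedFitResult,
    JointFitResult,
    count_parameters,
    min_predators,
    summarize_by_class,
)
from .transform import CalibrationCoefficients, DietMatrix

__all__ = ["evaluate_against_truth", "build_fit_report"]


def _values(x):
    if isinstance(x, (DietMatrix,)):
        return x.values
    if isinstance(x, CalibrationCoefficients):
        return x.values
    return np.asarray(x, dtype=float)


def _block_summary(errors: np.ndarray) -> dict:
    flat = errors.ravel()
    return {
        "max_abs_error": float(np.abs(flat).max()),
        "mean_error": float(flat.mean()),
        "rmse": float(np.sqrt((flat ** 2).mean())),
        "min_error": float(flat.min()),
        "max_error": float(flat.max()),
    }


def evaluate_against_truth(
    est_diet,
    true_diet,
    est_cc=None,
    true_cc=None,
) -> dict:
    """Signed errors and max-abs summaries per parameter block.

    Returns a dict with a ``diet`` block and, when coefficients are
    supplied, a ``cc`` block; each holds the signed error array
    (estimate minus truth) plus summary statistics, ready for export or
    histogramming.
    """
    de = _values(est_diet)
    dt = _values(true_diet)
    if de.shape != dt.shape:
        raise ValueError("estimated and true diet matrices differ in shape")
    out = {"diet": {"errors": de - dt, **_block_summary(de - dt)}}
    if (est_cc is None) != (true_cc is None):
        raise ValueError("supply both estimated and true coefficients, or neither")
    if est_cc is not None:
        ce, ct = _values(est_cc), _values(true_cc)
        if ce.shape != ct.shape:
            raise ValueError("estimated and true coefficients differ in length")
        out["cc"] = {"errors": ce - ct, **_block_summary(ce - ct)}
        out["max_abs_error"] = max(
            out["diet"]["max_abs_error"], out["cc"]["max_abs_error"]
        )
    else:
        out["max_abs_error"] = out["diet"]["max_abs_error"]
    return out


def build_fit_report(
    result,
    J: int,
    I: int,
    K: int,
    classes=None,
    truth: dict | None = None,
) -> dict:
    """Machine-readable report of a fit: counts recomputed from data.

    ``truth`` may hold ``diet``/``cc`` arrays from a simulation; when
    present an error-vs-truth summary is included.  A mismatch between
    the result's dimensions and (J, I, K) raises — reports never echo
    counts they have not verified.
    """
    diet = result.diet.values
    if diet.shape != (J, I):
        raise ValueError("diet matrix shape does not match the declared (J, I)")
    report = {
        "n_predators": J,
        "n_prey_types": I,
        "n_fatty_acids": K,
        "n_parameters": count_parameters(J, I, K),
        "degrees_of_freedom": J * (K - 1),
        "min_predators": min_predators(K, I),
        "objective": float(result.objective),
        "converged": bool(result.converged),
    }
    if isinstance(result, JointFitResult):
        if len(result.cc) != K:
            raise ValueError("coefficient length does not match the declared K")
        report.update(
            {
                "n_iterations": int(result.n_iterations),
                "kkt_residual": float(result.kkt_residual),
                "status": result.status,
                "start_objectives": [float(q) for q in result.start_objectives],
                "calibration_coefficients": result.cc.values.tolist(),
            }
        )
    elif isinstance(result, ConditionedFitResult):
        report["per_predator_objectives"] = result.objectives.tolist()
    if classes is not None and any(c is not None for c in classes):
        summary = summarize_by_class(result.diet, classes)
        report["class_summary"] = {
            cl: {
                "n": int(summary.counts[ci]),
                "mean": summary.means[ci].tolist(),
                "se": summary.ses[ci].tolist(),
            }
            for ci, cl in enumerate(summary.classes)
        }
    if truth is not None:
        est_cc = result.cc if isinstance(result, JointFitResult) else None
        ev = evaluate_against_truth(
            result.diet,
            truth["diet"],
            est_cc if "cc" in truth else None,
            truth.get("cc") if est_cc is not None else None,
        )
        report["error_vs_truth"] = {
            "max_abs_diet_error": ev["diet"]["max_abs_error"],
            "max_abs_cc_error": ev.get("cc", {}).get("max_abs_error"),
        }
    return report
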