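"""CSV readers/writers for signatures, diets and calibration coefficients.

All numeric matrices travel as CSV (diff-able, language-neutral) with
full double precision (Python's shortest round-trip float repr), so a
write/read cycle reproduces values exactly.  Signature files carry the
``K-1`` dietary fatty-acid columns; the augmentation slot is
reconstructed on load by the standard preprocessing pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .signatures import (
    AUG_LABEL,
    DEFAULT_REPLACEMENT,
    PredatorSample,
    PreyLibrary,
)
from .transform import CalibrationCoefficients, DietMatrix

__all__ = [
    "read_prey_csv",
    "write_prey_csv",
    "read_predator_csv",
    "write_predator_csv",
    "read_cc_csv",
    "write_cc_csv",
    "read_diet_csv",
    "write_diet_csv",
]

_NA = ["", "NA"]


def read_prey_csv(path, replacement: float = DEFAULT_REPLACEMENT) -> PreyLibrary:
    """Read ``prey_type, specimen_id, <fa_1>, ...`` rows into a library."""
    df = pd.read_csv(path, na_values=_NA, keep_default_na=False, float_precision="round_trip")
    return PreyLibrary.from_dataframe(df, replacement=replacement)


def write_prey_csv(library: PreyLibrary, path) -> None:
    """Write the dietary-subset columns (augmentation slot dropped)."""
    df = library.signatures
    cols = ["prey_type", "specimen_id"] + [
        c for c in library.labels if c != AUG_LABEL
    ]
    df[cols].to_csv(path, index=False)


def read_predator_csv(
    path,
    library: PreyLibrary | None = None,
    replacement: float = DEFAULT_REPLACEMENT,
) -> PredatorSample:
    """Read ``predator_id, class, <fa_1>, ...`` rows into a sample.

    When ``library`` is given, the fatty-acid columns are matched to the
    library's by name and reordered to the library's order; missing or
    extra columns raise.
    """
    df = pd.read_csv(path, na_values=_NA, keep_default_na=False, float_precision="round_trip")
    if library is not None:
        fa = [c for c in library.labels if c != AUG_LABEL]
        have = [c for c in df.columns if c not in ("predator_id", "class")]
        if set(have) != set(fa):
            missing = sorted(set(fa) - set(have))
            extra = sorted(set(have) - set(fa))
            raise ValueError(
                "predator fatty-acid columns do not match the prey library "
                f"(missing: {missing}, unexpected: {extra})"
            )
        meta = [c for c in ("predator_id", "class") if c in df.columns]
        df = df[meta + fa]
    return PredatorSample.from_dataframe(df, replacement=replacement)


def write_predator_csv(sample: PredatorSample, path) -> None:
    """Write the dietary-subset columns (augmentation slot dropped)."""
    keep = [k for k, lab in enumerate(sample.labels) if lab != AUG_LABEL]
    df = pd.DataFrame(
        sample.signatures[:, keep], columns=[sample.labels[k] for k in keep]
    )
    if sample.classes is not None:
        df.insert(0, "class", list(sample.classes))
    df.insert(0, "predator_id", list(sample.ids))
    df.to_csv(path, index=False)


def read_cc_csv(path) -> CalibrationCoefficients:
    """Read ``fatty_acid, coefficient`` rows (values taken verbatim)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"fatty_acid", "coefficient"}.issubset(df.columns):
        raise ValueError("coefficient table needs 'fatty_acid' and 'coefficient' columns")
    vals = df["coefficient"].to_numpy(dtype=float)
    if np.any(vals <= 0.0):
        raise ValueError("calibration coefficients must be strictly positive")
    return CalibrationCoefficients(
        vals,
        lower_bound=min(0.02, float(vals.min())),
        sum_constraint=float(vals.sum()),
    )


def write_cc_csv(cc: CalibrationCoefficients, path, labels=None) -> None:
    vals = cc.values if isinstance(cc, CalibrationCoefficients) else np.asarray(cc, float)
    if labels is None:
        labels = [f"fa_{k + 1}" for k in range(vals.size - 1)] + [AUG_LABEL]
    pd.DataFrame({"fatty_acid": list(labels), "coefficient": vals}).to_csv(
        path, index=False
    )


def read_diet_csv(path) -> DietMatrix:
    """Read a ``predator_id`` x prey-type proportion table."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "predator_id" not in df.columns:
        raise ValueError("diet table needs a 'predator_id' column")
    prey = [c for c in df.columns if c != "predator_id"]
    return DietMatrix(
        df[prey].to_numpy(dtype=float),
        prey_types=tuple(prey),
        predator_ids=tuple(df["predator_id"].astype(str)),
    )


def write_diet_csv(diet: DietMatrix, path) -> None:
    prey = diet.prey_types or tuple(f"prey_{i + 1}" for i in range(diet.shape[1]))
    ids = diet.predator_ids or tuple(f"pred_{j + 1}" for j in range(diet.shape[0]))
    df = pd.DataFrame(diet.values, columns=list(prey))
    df.insert(0, "predator_id", list(ids))
    df.to_csv(path, index=False)
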