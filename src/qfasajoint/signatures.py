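"""Compositional fatty-acid signature types and Aitchison geometry.

A *signature* is a vector of fatty-acid proportions on the unit simplex
describing the lipid composition of one tissue sample.  Quantitative
fatty acid signature analysis (QFASA) models predator signatures as
mixtures of prey signatures, and measures discrepancy between
signatures in the Aitchison geometry of compositional data: Euclidean
distance between centred log-ratio (clr) transforms.

Preprocessing follows standard QFASA conventions:

* proportions that are missing or zero are replaced by a small constant
  (default 0.005) so that log-ratio quantities are defined;
* each signature over the dietary fatty-acid subset is augmented with an
  extra component equal to one minus the subset sum, so the full
  ``K``-part vector closes to 1 (the augmentation slot is an ordinary
  component thereafter and participates in all distances).

The preprocessing order is: (1) replace zeros/missing in the dietary
subset, (2) compute the augmentation component from the *original*
(pre-replacement) subset sum, (3) reclose the full vector.  This keeps
the augmentation faithful to the measured mass while guaranteeing
strictly positive output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_REPLACEMENT",
    "CLOSURE_ATOL",
    "Signature",
    "PreyLibrary",
    "PredatorSample",
    "closure",
    "clr",
    "geometric_mean",
    "aitchison_sq_distance",
    "replace_zeros",
    "augment_signature",
    "preprocess_signature",
]

#: default constant substituted for zero / missing proportions
DEFAULT_REPLACEMENT = 0.005
#: tolerance on the unit sum of a closed signature
CLOSURE_ATOL = 1e-9
#: tolerance accepted on raw input sums (CSV round-tripping at ~6 decimals)
INPUT_SUM_ATOL = 1e-6

AUG_LABEL = "aug"


def closure(values, axis: int = -1) -> np.ndarray:
    """Renormalise a positive array so it sums to one along ``axis``."""
    x = np.asarray(values, dtype=float)
    total = x.sum(axis=axis, keepdims=True)
    if np.any(total <= 0.0):
        raise ValueError("cannot close a vector with non-positive total")
    return x / total


def _proportions(sig) -> np.ndarray:
    if isinstance(sig, Signature):
        return sig.proportions
    return np.asarray(sig, dtype=float)


def geometric_mean(sig) -> float:
    """Geometric mean of the proportions of one signature."""
    x = _proportions(sig)
    if x.size == 0 or np.any(x <= 0.0):
        raise ValueError("geometric mean requires strictly positive proportions")
    return float(np.exp(np.mean(np.log(x))))


def clr(values, axis: int = -1) -> np.ndarray:
    """Centred log-ratio transform, ``log x - mean(log x)``.

    Invariant under rescaling of ``values``, so closure beforehand is
    optional.
    """
    x = np.asarray(values, dtype=float)
    if np.any(x <= 0.0):
        raise ValueError("clr requires strictly positive proportions")
    logx = np.log(x)
    return logx - logx.mean(axis=axis, keepdims=True)


def aitchison_sq_distance(a, b) -> float:
    """Squared Aitchison distance between two compositions.

    This is exactly the per-predator term of the model objective:
    ``sum_k [log(a_k/gm(a)) - log(b_k/gm(b))]**2``.
    """
    xa, xb = _proportions(a), _proportions(b)
    if xa.shape != xb.shape:
        raise ValueError("signatures must have the same length")
    d = clr(xa) - clr(xb)
    return float(np.dot(d, d))


def replace_zeros(raw, replacement: float = DEFAULT_REPLACEMENT) -> np.ndarray:
    """Replace zero and missing proportions by a small positive constant."""
    if replacement <= 0.0:
        raise ValueError("replacement must be positive")
    x = np.asarray(raw, dtype=float)
    missing = ~np.isfinite(x)
    if np.any(x[~missing] < 0.0):
        raise ValueError("signature proportions must be non-negative")
    bad = missing | (x == 0.0)
    if bad.all():
        raise ValueError("empty signature: all proportions zero or missing")
    out = x.copy()
    out[bad] = replacement
    return out


def _default_labels(n: int) -> tuple[str, ...]:
    return tuple(f"fa_{i + 1}" for i in range(n))


def augment_signature(
    subset,
    labels: Sequence[str] | None = None,
    replacement: float = DEFAULT_REPLACEMENT,
    subset_sum: float | None = None,
    aug_label: str = AUG_LABEL,
) -> "Signature":
    """Append the augmentation component ``1 - sum(subset)`` and close.

    ``subset`` holds the (already strictly positive) dietary fatty-acid
    proportions.  ``subset_sum`` optionally supplies the pre-replacement
    subset total so that zero replacement does not inflate the measured
    mass.  If the subset sums to one (augmentation component would be
    non-positive) the component is set to ``replacement`` and the vector
    reclosed, mirroring the zero-replacement rule.
    """
    x = np.asarray(subset, dtype=float)
    if np.any(x <= 0.0):
        raise ValueError("augmentation requires strictly positive proportions")
    total = float(x.sum()) if subset_sum is None else float(subset_sum)
    if total > 1.0 + INPUT_SUM_ATOL:
        raise ValueError("proportions exceed unity")
    extra = 1.0 - total
    if extra <= 0.0:
        extra = replacement
    full = np.append(x, extra)
    if labels is None:
        labels = _default_labels(x.size)
    return Signature(closure(full), tuple(labels) + (aug_label,))


def preprocess_signature(
    raw,
    labels: Sequence[str] | None = None,
    replacement: float = DEFAULT_REPLACEMENT,
    augment: bool = True,
    aug_label: str = AUG_LABEL,
) -> "Signature":
    """Full preprocessing pipeline for one raw signature.

    Zeros and missing values are replaced by ``replacement``; when
    ``augment`` is true the augmentation component is computed from the
    original subset sum and appended; the result is closed to 1.
    """
    x = np.asarray(raw, dtype=float)
    if labels is None:
        labels = _default_labels(x.size)
    elif len(labels) != x.size:
        raise ValueError("labels and proportions must have equal length")
    filled = replace_zeros(x, replacement)
    if augment:
        original_sum = float(np.where(np.isfinite(x), x, 0.0).sum())
        return augment_signature(
            filled, labels, replacement, subset_sum=original_sum, aug_label=aug_label
        )
    return Signature(closure(filled), tuple(labels))


@dataclass(frozen=True)
class Signature:
    """One specimen's composition over ``K`` fatty-acid slots.

    Proportions are strictly positive and sum to one within
    :data:`CLOSURE_ATOL`; construct via :func:`preprocess_signature` for
    raw data.
    """

    proportions: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        props = np.asarray(self.proportions, dtype=float)
        object.__setattr__(self, "proportions", props)
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        if props.ndim != 1:
            raise ValueError("signature proportions must be one-dimensional")
        if len(labels) != props.size:
            raise ValueError("labels and proportions must have equal length")
        if np.any(props <= 0.0):
            raise ValueError("signature proportions must be strictly positive")
        if abs(props.sum() - 1.0) > CLOSURE_ATOL:
            raise ValueError("signature proportions must sum to 1")

    def __len__(self) -> int:
        return self.proportions.size


def _check_rows(matrix: np.ndarray, what: str) -> None:
    if np.any(matrix <= 0.0):
        raise ValueError(f"{what} must be strictly positive after preprocessing")
    if np.any(np.abs(matrix.sum(axis=1) - 1.0) > CLOSURE_ATOL):
        raise ValueError(f"each {what} row must sum to 1")


@dataclass
class PreyLibrary:
    """Prey-type-labelled signatures plus per-type mean signatures.

    ``signatures`` is a tidy frame with columns ``prey_type``,
    ``specimen_id`` and one column per fatty-acid slot (all ``K`` slots,
    preprocessed).  ``mean_signatures`` holds the per-type arithmetic
    mean of the specimen signatures, reclosed to the simplex, one row
    per prey type in ``prey_types`` order.
    """

    signatures: pd.DataFrame
    mean_signatures: np.ndarray
    prey_types: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.mean_signatures = np.asarray(self.mean_signatures, dtype=float)
        self.prey_types = tuple(str(t) for t in self.prey_types)
        self.labels = tuple(self.labels)
        if len(self.prey_types) < 2:
            raise ValueError("a prey library needs at least two prey types")
        if self.mean_signatures.shape != (len(self.prey_types), len(self.labels)):
            raise ValueError("mean_signatures must be I x K")
        _check_rows(self.mean_signatures, "mean signature")
        counts = self.signatures["prey_type"].value_counts()
        for t in self.prey_types:
            if counts.get(t, 0) < 1:
                raise ValueError(f"prey type {t!r} has no specimens")

    @property
    def n_types(self) -> int:
        return len(self.prey_types)

    @property
    def n_fatty_acids(self) -> int:
        return len(self.labels)

    @classmethod
    def from_matrix(
        cls,
        matrix,
        prey_type_of_row: Sequence[str],
        labels: Sequence[str],
        specimen_ids: Sequence[str] | None = None,
    ) -> "PreyLibrary":
        """Build a library from preprocessed ``K``-length signature rows."""
        matrix = np.asarray(matrix, dtype=float)
        types_of_row = [str(t) for t in prey_type_of_row]
        if matrix.ndim != 2 or matrix.shape[0] != len(types_of_row):
            raise ValueError("matrix rows and prey_type_of_row must align")
        _check_rows(matrix, "signature")
        if specimen_ids is None:
            specimen_ids = [f"spec_{i + 1}" for i in range(matrix.shape[0])]
        # prey types ordered by first appearance
        prey_types = tuple(dict.fromkeys(types_of_row))
        means = np.vstack(
            [
                closure(matrix[[t == pt for t in types_of_row]].mean(axis=0))
                for pt in prey_types
            ]
        )
        frame = pd.DataFrame(matrix, columns=list(labels))
        frame.insert(0, "specimen_id", list(specimen_ids))
        frame.insert(0, "prey_type", types_of_row)
        return cls(frame, means, prey_types, tuple(labels))

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        replacement: float = DEFAULT_REPLACEMENT,
        aug_label: str = AUG_LABEL,
    ) -> "PreyLibrary":
        """Build a library from raw dietary-subset rows (CSV schema).

        Expects columns ``prey_type``, ``specimen_id`` and one column
        per dietary fatty acid; each row is preprocessed (zero
        replacement, augmentation, closure).
        """
        required = {"prey_type", "specimen_id"}
        if not required.issubset(df.columns):
            raise ValueError("prey table needs 'prey_type' and 'specimen_id' columns")
        fa_cols = [c for c in df.columns if c not in required]
        if not fa_cols:
            raise ValueError("prey table has no fatty-acid columns")
        sigs = [
            preprocess_signature(
                row, fa_cols, replacement=replacement, aug_label=aug_label
            ).proportions
            for row in df[fa_cols].to_numpy(dtype=float)
        ]
        return cls.from_matrix(
            np.vstack(sigs),
            df["prey_type"].tolist(),
            tuple(fa_cols) + (aug_label,),
            df["specimen_id"].tolist(),
        )


@dataclass
class PredatorSample:
    """Predator signatures with ids and optional class labels.

    Fatty-acid ``labels`` must be identical (same order) to the prey
    library the sample is analysed against; :func:`qfasajoint.estimation
    .fit_joint` enforces this.
    """

    signatures: np.ndarray
    ids: tuple[str, ...]
    labels: tuple[str, ...]
    classes: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.signatures = np.asarray(self.signatures, dtype=float)
        self.ids = tuple(str(i) for i in self.ids)
        self.labels = tuple(self.labels)
        if self.signatures.ndim != 2:
            raise ValueError("predator signatures must be a J x K matrix")
        J, K = self.signatures.shape
        if len(self.ids) != J:
            raise ValueError("one id per predator required")
        if len(self.labels) != K:
            raise ValueError("one label per fatty-acid slot required")
        _check_rows(self.signatures, "predator signature")
        if self.classes is not None:
            self.classes = tuple(
                None if c is None or (isinstance(c, float) and np.isnan(c)) else str(c)
                for c in self.classes
            )
            if len(self.classes) != J:
                raise ValueError("one class label per predator required")

    @property
    def n_predators(self) -> int:
        return self.signatures.shape[0]

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        replacement: float = DEFAULT_REPLACEMENT,
        aug_label: str = AUG_LABEL,
    ) -> "PredatorSample":
        """Build a sample from raw dietary-subset rows (CSV schema)."""
        if "predator_id" not in df.columns:
            raise ValueError("predator table needs a 'predator_id' column")
        meta = {"predator_id", "class"}
        fa_cols = [c for c in df.columns if c not in meta]
        if not fa_cols:
            raise ValueError("predator table has no fatty-acid columns")
        sigs = [
            preprocess_signature(
                row, fa_cols, replacement=replacement, aug_label=aug_label
            ).proportions
            for row in df[fa_cols].to_numpy(dtype=float)
        ]
        classes = tuple(df["class"]) if "class" in df.columns else None
        return cls(
            np.vstack(sigs),
            tuple(df["predator_id"].astype(str)),
            tuple(fa_cols) + (aug_label,),
            classes,
        )
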