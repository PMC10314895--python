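"""Protein quantification matrices and sample-design tables.

A quant matrix is a :class:`pandas.DataFrame` of nonnegative intensities
(or ``NaN`` for missing values) indexed by ``protein_id`` with one column
per sample, the shape a DIA-MS quantification export takes after
protein-level rollup.  A sample design is a DataFrame with columns
``sample_id``, ``arm`` and ``experiment_id`` mapping each sample to its
treatment arm and replicate experiment.

Files are plain TSV: first column ``protein_id``, remaining columns
samples; empty cells or ``NA`` denote missing values.  IDs are never
quoted.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QuantFormatError",
    "read_quant_table",
    "write_quant_table",
    "read_design_table",
    "write_design_table",
    "validate_quant_matrix",
    "validate_design",
    "log2_transform",
    "median_normalize",
    "filter_min_detection",
    "intersect_proteins",
    "arm_samples",
]

DESIGN_COLUMNS = ("sample_id", "arm", "experiment_id")


class QuantFormatError(ValueError):
    """Raised for malformed quant matrices or design tables."""


def validate_quant_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    if matrix.index.name != "protein_id":
        raise QuantFormatError("quant matrix index must be named 'protein_id'")
    if matrix.index.duplicated().any():
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise QuantFormatError(f"duplicate protein IDs: {dupes[:5]}")
    if matrix.columns.duplicated().any():
        dupes = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise QuantFormatError(f"duplicate sample IDs: {dupes[:5]}")
    values = matrix.to_numpy(dtype=float)
    if np.nanmin(values, initial=0.0) < 0:
        raise QuantFormatError("negative intensities are not allowed")
    return matrix


def read_quant_table(path) -> pd.DataFrame:
    """Read a protein x sample TSV into a quant matrix.

    Empty cells and ``NA`` are treated as missing.  Duplicate protein or
    sample IDs and negative values raise :class:`QuantFormatError`.
    """
    matrix = pd.read_csv(
        path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False,
        dtype={0: str},
    )
    if matrix.index.name != "protein_id":
        raise QuantFormatError(
            f"first column must be 'protein_id', got {matrix.index.name!r}"
        )
    matrix = matrix.astype(float)
    return validate_quant_matrix(matrix)


def write_quant_table(matrix: pd.DataFrame, path) -> None:
    validate_quant_matrix(matrix)
    matrix.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")


def validate_design(design: pd.DataFrame, matrix: pd.DataFrame | None = None) -> pd.DataFrame:
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise QuantFormatError(f"design table missing columns: {missing}")
    if design["sample_id"].duplicated().any():
        raise QuantFormatError("duplicate sample IDs in design table")
    if matrix is not None:
        unknown = set(matrix.columns) - set(design["sample_id"])
        if unknown:
            raise QuantFormatError(f"samples without a design row: {sorted(unknown)[:5]}")
    return design


def read_design_table(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype=str)
    return validate_design(design)


def write_design_table(design: pd.DataFrame, path) -> None:
    validate_design(design)
    design.to_csv(path, sep="\t", index=False)


def arm_samples(design: pd.DataFrame, arm: str) -> list[str]:
    """Sample IDs belonging to a treatment arm."""
    samples = design.loc[design["arm"] == arm, "sample_id"].tolist()
    if not samples:
        raise KeyError(f"arm {arm!r} not present in design")
    return samples


def log2_transform(matrix: pd.DataFrame, zero_floor: float = 1.0) -> pd.DataFrame:
    """Log2-transform intensities, preserving missingness.

    Zeros are floored at ``zero_floor`` (default 1, i.e. mapped to 0 on the
    log2 scale) because DIA exports can contain exact zeros; negative
    values raise.
    """
    values = matrix.to_numpy(dtype=float)
    if np.nanmin(values, initial=0.0) < 0:
        raise QuantFormatError("cannot log2-transform negative intensities")
    floored = np.where(values < zero_floor, zero_floor, values)
    floored = np.where(np.isnan(values), np.nan, floored)
    return pd.DataFrame(np.log2(floored), index=matrix.index, columns=matrix.columns)


def median_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center each sample's median (log2 scale) on the global median.

    Idempotent; preserves within-sample relative differences exactly.
    A sample with no observed values cannot be normalized and raises.
    """
    all_missing = matrix.isna().all(axis=0)
    if all_missing.any():
        bad = matrix.columns[all_missing].tolist()
        raise QuantFormatError(f"sample(s) with all values missing: {bad}")
    sample_medians = matrix.median(axis=0, skipna=True)
    target = float(np.median(sample_medians.to_numpy()))
    return matrix.sub(sample_medians - target, axis=1)


def filter_min_detection(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    min_per_arm: int = 2,
    arms: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Keep proteins with >= ``min_per_arm`` observed values in every arm.

    ``arms`` restricts the requirement to the arms under comparison
    (default: every arm in the design).
    """
    if min_per_arm < 2:
        raise ValueError("min_per_arm must be >= 2 for valid group tests")
    validate_design(design)
    if arms is None:
        arms = list(dict.fromkeys(design["arm"]))
    keep = pd.Series(True, index=matrix.index)
    for arm in arms:
        cols = [s for s in arm_samples(design, arm) if s in matrix.columns]
        keep &= matrix[cols].notna().sum(axis=1) >= min_per_arm
    return matrix.loc[keep]


def intersect_proteins(matrix_a: pd.DataFrame, matrix_b: pd.DataFrame) -> list[str]:
    """Sorted intersection of the two matrices' protein ID sets."""
    return sorted(set(matrix_a.index) & set(matrix_b.index))
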