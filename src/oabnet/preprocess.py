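"""Score-matrix extraction and standardization.

Clustering and PCA operate on the n × 5 matrix of total scores (one
column per timepoint), z-scored per column with the population SD
(divisor n) so the behaviour is identical to the conventional
``StandardScaler``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cohort import Cohort
from .errors import FormatError, ValidationError


@dataclass
class ScoreMatrix:
    """Patients × timepoints score matrix with a standardization flag."""

    patient_ids: list[str]
    values: np.ndarray  # (n, 5)
    standardized: bool = False

    @property
    def n(self) -> int:
        return self.values.shape[0]


def extract_totals(cohort: Cohort) -> ScoreMatrix:
    """Total scores at all five timepoints, rows in cohort order."""
    if cohort.n_patients == 0:
        raise FormatError("cohort is empty")
    return ScoreMatrix(cohort.patient_ids, cohort.totals(), standardized=False)


def standardize(matrix: ScoreMatrix) -> ScoreMatrix:
    """Per-column z-scores using the population SD (divisor n).

    Constant columns carry no information for a Euclidean analysis; they
    map to all-zeros with a warning rather than dividing by zero.
    Idempotent on non-constant columns.
    """
    if matrix.n < 2:
        raise ValidationError("standardization requires at least 2 rows")
    values = np.asarray(matrix.values, dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0)  # population SD, ddof=0
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant column(s) standardized to zeros",
            stacklevel=2,
        )
    safe_sd = np.where(constant, 1.0, sd)
    z = (values - mean) / safe_sd
    z[:, constant] = 0.0
    return ScoreMatrix(list(matrix.patient_ids), z, standardized=True)
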