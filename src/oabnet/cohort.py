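"""Patient cohort container and CSV input/output.

A cohort is a wide table of OABSS measurements: one row per patient, one
block of columns per follow-up timepoint.  The OABSS instrument has four
items — Q1 daytime frequency (0–2), Q2 nighttime frequency (0–3), Q3
urgency (0–5), Q4 urgency incontinence (0–5) — whose sum is the total
score (0–15).  Two CSV dialects are supported:

* the *component* dialect, columns ``T0-Q1 … T24-Q4`` (plus derived
  ``T0-OABSS …`` totals), which carries full item-level information; and
* the *totals* dialect, columns ``T0-OABSS … T24-OABSS``, carrying only
  total scores.  Item-level analyses are unavailable for such inputs.

An optional ``true_cluster`` integer column records planted ground-truth
group membership for synthetic cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

TIMEPOINTS: tuple[str, ...] = ("T0", "T6", "T12", "T18", "T24")
FOLLOWUPS: tuple[str, ...] = ("T6", "T12", "T18", "T24")
COMPONENTS: tuple[str, ...] = ("Q1", "Q2", "Q3", "Q4")

#: inclusive (low, high) score bounds per OABSS item
COMPONENT_BOUNDS: dict[str, tuple[int, int]] = {
    "Q1": (0, 2),
    "Q2": (0, 3),
    "Q3": (0, 5),
    "Q4": (0, 5),
}
TOTAL_BOUNDS: tuple[int, int] = (0, 15)


def component_column(timepoint: str, component: str) -> str:
    return f"{timepoint}-{component}"


def total_column(timepoint: str) -> str:
    return f"{timepoint}-OABSS"


COMPONENT_COLUMNS = [component_column(t, c) for t in TIMEPOINTS for c in COMPONENTS]
TOTAL_COLUMNS = [total_column(t) for t in TIMEPOINTS]


@dataclass
class Cohort:
    """Wide-format cohort table.

    Parameters
    ----------
    data
        DataFrame with a ``patient_id`` column, total-score columns for all
        five timepoints, component columns when ``has_components`` is true,
        and optionally ``true_cluster``.
    has_components
        Whether item-level (Q1..Q4) columns are present.
    integer_scores
        Whether scores are integral (real questionnaire data).  Synthetic
        cohorts generated without discretisation carry real-valued scores
        and set this to False; bound/integrality validation is then skipped.
    """

    data: pd.DataFrame
    has_components: bool = True
    integer_scores: bool = True

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ---------------------------------------------------------

    @property
    def n_patients(self) -> int:
        return len(self.data)

    @property
    def patient_ids(self) -> list[str]:
        return self.data["patient_id"].astype(str).tolist()

    @property
    def true_cluster(self) -> np.ndarray | None:
        if "true_cluster" in self.data.columns:
            return self.data["true_cluster"].to_numpy(dtype=int)
        return None

    def totals(self) -> np.ndarray:
        """n_patients × 5 array of total scores, columns ordered T0..T24."""
        return self.data[TOTAL_COLUMNS].to_numpy(dtype=float)

    def components_at(self, timepoint: str) -> np.ndarray:
        """n_patients × 4 array of Q1..Q4 scores at one timepoint."""
        _check_timepoint(timepoint)
        if not self.has_components:
            raise FormatError(
                "cohort carries total scores only; component scores are "
                f"required for timepoint {timepoint}"
            )
        cols = [component_column(timepoint, c) for c in COMPONENTS]
        return self.data[cols].to_numpy(dtype=float)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        df = self.data
        if "patient_id" not in df.columns:
            raise FormatError("missing required column 'patient_id'")
        if df["patient_id"].duplicated().any():
            dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
            raise ValidationError(f"duplicate patient_id {dup!r}")
        for col in TOTAL_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"missing timepoint column {col!r}")
        if self.has_components:
            for col in COMPONENT_COLUMNS:
                if col not in df.columns:
                    raise FormatError(f"missing timepoint column {col!r}")
        if len(df) and df[TOTAL_COLUMNS].isna().any().any():
            bad = df.loc[df[TOTAL_COLUMNS].isna().any(axis=1), "patient_id"].iloc[0]
            raise ValidationError(f"missing total score for patient {bad!r}")
        if self.integer_scores:
            self._validate_bounds()
        if self.has_components:
            self._validate_sums()

    def _validate_bounds(self) -> None:
        df = self.data
        checks: list[tuple[str, int, int]] = [
            (total_column(t), *TOTAL_BOUNDS) for t in TIMEPOINTS
        ]
        if self.has_components:
            checks += [
                (component_column(t, c), *COMPONENT_BOUNDS[c])
                for t in TIMEPOINTS
                for c in COMPONENTS
            ]
        for col, lo, hi in checks:
            vals = df[col].to_numpy(dtype=float)
            if len(vals) == 0:
                continue
            if not np.all(vals == np.round(vals)):
                bad = df.loc[vals != np.round(vals), "patient_id"].iloc[0]
                raise ValidationError(f"non-integer score in {col} for patient {bad!r}")
            out = (vals < lo) | (vals > hi)
            if out.any():
                bad = df.loc[out, "patient_id"].iloc[0]
                raise ValidationError(
                    f"score out of bounds [{lo}, {hi}] in {col} for patient {bad!r}"
                )

    def _validate_sums(self) -> None:
        df = self.data
        for t in TIMEPOINTS:
            comp_sum = sum(
                df[component_column(t, c)].to_numpy(dtype=float) for c in COMPONENTS
            )
            tot = df[total_column(t)].to_numpy(dtype=float)
            mismatch = ~np.isclose(comp_sum, tot, atol=1e-9)
            if len(df) and mismatch.any():
                bad = df.loc[mismatch, "patient_id"].iloc[0]
                raise ValidationError(
                    f"total at {t} does not equal Q1+Q2+Q3+Q4 for patient {bad!r}"
                )


def _check_timepoint(timepoint: str) -> None:
    if timepoint not in TIMEPOINTS:
        raise ValidationError(
            f"unknown timepoint {timepoint!r}; expected one of {TIMEPOINTS}"
        )


# -- CSV I/O ---------------------------------------------------------------


def write_cohort_csv(cohort: Cohort, path) -> None:
    """Write a cohort in its native dialect (components when available)."""
    cols = ["patient_id"]
    if cohort.has_components:
        cols += COMPONENT_COLUMNS
    cols += TOTAL_COLUMNS
    if "true_cluster" in cohort.data.columns:
        cols.append("true_cluster")
    cohort.data[cols].to_csv(path, index=False)


def read_cohort_csv(path) -> Cohort:
    """Read either CSV dialect, sniffing by header.

    Raises :class:`FormatError` when required timepoint columns are
    missing and :class:`ValidationError` (naming the patient row) when a
    score violates the instrument bounds.
    """
    df = pd.read_csv(path)
    if "patient_id" not in df.columns:
        raise FormatError("missing required column 'patient_id'")
    df["patient_id"] = df["patient_id"].astype(str)

    has_components = any(col in df.columns for col in COMPONENT_COLUMNS)
    if has_components:
        for col in COMPONENT_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"missing timepoint column {col!r}")
        # totals are derived when absent, validated when present
        for t in TIMEPOINTS:
            tc = total_column(t)
            if tc not in df.columns:
                df[tc] = sum(df[component_column(t, c)] for c in COMPONENTS)
    else:
        for col in TOTAL_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"missing timepoint column {col!r}")
    return Cohort(df, has_components=has_components)
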