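"""Change-from-baseline summaries per OABSS item and total.

For each follow-up t the per-patient change is score(t) − score(T0);
the cohort summary reports mean and sample SD (divisor n−1) of those
changes.  Improvement is a *negative* change.  By linearity the mean
total change equals the sum of the item mean changes exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import COMPONENTS, FOLLOWUPS, Cohort, component_column, total_column
from .errors import ValidationError

SEVERITY_BANDS = "mild: <5, moderate: 6-11, severe: >=12 (5 unclassified)"


@dataclass
class ChangeSummary:
    """Mean ± SD change from baseline, per measure and follow-up."""

    frame: pd.DataFrame  # index: T6..T24; columns: MultiIndex (measure, stat)
    n: int
    measures: tuple[str, ...]

    def mean(self, measure: str, timepoint: str) -> float:
        return float(self.frame.loc[timepoint, (measure, "mean")])

    def sd(self, measure: str, timepoint: str) -> float:
        return float(self.frame.loc[timepoint, (measure, "sd")])

    def to_table(self) -> pd.DataFrame:
        """Layout with one "mean ± sd" cell per measure and follow-up."""
        out = pd.DataFrame(index=list(self.frame.index))
        out.index.name = "timepoint"
        for m in self.measures:
            out[m] = [
                f"{self.frame.loc[t, (m, 'mean')]:+.4f} ± "
                f"{self.frame.loc[t, (m, 'sd')]:.4f}"
                for t in self.frame.index
            ]
        return out


def change_summary(cohort: Cohort) -> ChangeSummary:
    """Summarise changes from baseline over the cohort.

    Component-level rows require the component dialect; totals-only
    cohorts yield a total-only summary.
    """
    if cohort.n_patients < 2:
        raise ValidationError("change summary requires at least 2 patients")
    measures = list(COMPONENTS) + ["total"] if cohort.has_components else ["total"]
    data = {}
    for m in measures:
        col = (lambda t: component_column(t, m)) if m != "total" else total_column
        baseline = cohort.data[col("T0")].to_numpy(dtype=float)
        for t in FOLLOWUPS:
            change = cohort.data[col(t)].to_numpy(dtype=float) - baseline
            data[(m, "mean")] = data.get((m, "mean"), {})
            data[(m, "sd")] = data.get((m, "sd"), {})
            data[(m, "mean")][t] = float(change.mean())
            data[(m, "sd")][t] = float(change.std(ddof=1))
    frame = pd.DataFrame(
        {key: [vals[t] for t in FOLLOWUPS] for key, vals in data.items()},
        index=list(FOLLOWUPS),
    )
    frame.columns = pd.MultiIndex.from_tuples(frame.columns)
    return ChangeSummary(frame=frame, n=cohort.n_patients, measures=tuple(measures))


def severity_band(total: int) -> str:
    """OABSS severity band; a total of exactly 5 is outside the published
    bands and is labelled "unclassified"."""
    if not float(total) == int(total) or not 0 <= int(total) <= 15:
        raise ValidationError(f"total score must be an integer in [0, 15]; got {total}")
    total = int(total)
    if total < 5:
        return "mild"
    if total == 5:
        return "unclassified"
    if total <= 11:
        return "moderate"
    return "severe"
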