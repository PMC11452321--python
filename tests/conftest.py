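import numpy as np
import pandas as pd
import pytest

from oabnet.cohort import COMPONENTS, TIMEPOINTS, Cohort, component_column, total_column
from oabnet.simulate import generate_cohort, study_sizes_preset, table1_calibrated_preset


def make_component_cohort(scores: dict[str, dict[str, list[int]]]) -> Cohort:
    """Build a component-dialect cohort from {patient_id: {tp: [q1..q4]}}."""
    rows = []
    for pid, per_tp in scores.items():
        row = {"patient_id": pid}
        for t in TIMEPOINTS:
            comps = per_tp[t]
            for c, v in zip(COMPONENTS, comps):
                row[component_column(t, c)] = v
            row[total_column(t)] = sum(comps)
        rows.append(row)
    return Cohort(pd.DataFrame(rows), has_components=True)


def make_totals_cohort(totals: dict[str, list[float]]) -> Cohort:
    """Build a totals-dialect cohort from {patient_id: [T0..T24 totals]}."""
    rows = []
    for pid, vals in totals.items():
        row = {"patient_id": pid}
        for t, v in zip(TIMEPOINTS, vals):
            row[total_column(t)] = v
        rows.append(row)
    columns = ["patient_id"] + [total_column(t) for t in TIMEPOINTS]
    return Cohort(pd.DataFrame(rows, columns=columns), has_components=False)


@pytest.fixture(scope="session")
def study_cohort():
    return generate_cohort(study_sizes_preset(seed=42))


@pytest.fixture(scope="session")
def table1_cohort():
    return generate_cohort(table1_calibrated_preset(seed=42))


@pytest.fixture
def tiny_cohort():
    """Three patients with hand-picked component scores."""
    return make_component_cohort(
        {
            "A": {t: [1, 2, 3, 2] for t in TIMEPOINTS},
            "B": {
                "T0": [2, 3, 5, 4],
                "T6": [2, 2, 4, 3],
                "T12": [1, 2, 3, 2],
                "T18": [1, 1, 2, 1],
                "T24": [1, 1, 1, 1],
            },
            "C": {
                "T0": [0, 1, 1, 0],
                "T6": [0, 1, 2, 1],
                "T12": [1, 1, 2, 2],
                "T18": [1, 2, 3, 3],
                "T24": [2, 2, 4, 4],
            },
        }
    )
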