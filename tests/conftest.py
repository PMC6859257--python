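"""Shared fixtures: tiny hand-checkable cohorts and pair builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pairscreen.data_model import CleanPair, CrudeDatabase


def make_pair(x, y, px="PX", py="PY", t=0, pop="VII") -> CleanPair:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ids = tuple(f"S{i:03d}" for i in range(x.size))
    return CleanPair(x, y, ids, px, py, t, pop)


def build_db(parameters, time_grid, subject_rows, measurements):
    """Small-database builder.

    ``subject_rows``: list of (subject_id, treatment, survival, study);
    ``measurements``: list of (subject_id, time, parameter, value).
    """
    subjects = pd.DataFrame(
        [{"treatment": tr, "survival": sv, "study": st}
         for _, tr, sv, st in subject_rows],
        index=pd.Index([sid for sid, *_ in subject_rows],
                       name="subject_id"))
    meas = pd.DataFrame(measurements,
                        columns=["subject_id", "time", "parameter", "value"])
    return CrudeDatabase.from_frames(parameters, time_grid, subjects, meas)


@pytest.fixture
def four_subject_db():
    """2 treated survivors, 1 treated non-survivor, 1 control survivor."""
    rows = [("A", "treated", "survivor", "ST01"),
            ("B", "treated", "survivor", "ST01"),
            ("C", "treated", "non-survivor", "ST02"),
            ("D", "control", "survivor", "ST02")]
    meas = [(s, 0, p, v) for s, p, v in [
        ("A", "P1", 1.0), ("A", "P2", 2.0),
        ("B", "P1", 3.0), ("B", "P2", 4.0),
        ("C", "P1", 5.0), ("C", "P2", 6.0),
        ("D", "P1", 7.0), ("D", "P2", 8.0)]]
    return build_db(["P1", "P2"], [0], rows, meas)


@pytest.fixture
def disjoint_missing_db():
    """6 subjects, 2 parameters, one missing cell each, disjoint subjects.

    P1 is missing for S1 and P2 for S2, so each parameter has 5 values
    and the pairwise-complete intersection has 4.
    """
    rows = [(f"S{i}", "treated", "survivor", "ST01") for i in range(1, 7)]
    meas = []
    for i in range(1, 7):
        if i != 1:
            meas.append((f"S{i}", 0, "P1", float(i)))
        if i != 2:
            meas.append((f"S{i}", 0, "P2", float(10 + i)))
    return build_db(["P1", "P2"], [0], rows, meas)
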