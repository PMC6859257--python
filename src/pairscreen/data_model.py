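"""The crude database: long-format measurements plus subject classifiers.

The screen starts from a minimally curated pool of measurements from
many small studies — one row per (subject, time point, parameter) — and
four per-subject group classifiers: G1 treatment (treated/control), G2
survival (survivor/non-survivor), G3 the subject id itself, G4 the
study id.  Crossing the treatment and survival classifiers (each value
or "any") yields seven canonical populations I–VII; the two strata that
would mix treatment arms within a survival outcome are not used.

Pairwise analyses never impute: for a parameter pair at one time point
in one population, only subjects with *both* values present enter the
two equal-length "clean vectors".  The per-pair sample sizes form the
symmetric sample-size matrix that postprocessing later filters on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import IntegrityError, SchemaError, UnknownIdentifierError

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_TIME_GRID", "MISSING_TOKENS", "PopulationDef", "SubjectRecord",
    "CleanPair", "CrudeDatabase", "canonical_populations", "load_database",
    "write_database",
]

#: Minutes after treatment at which the study grid samples (0–300 min).
DEFAULT_TIME_GRID = (0, 60, 120, 180, 240, 300)

#: Cell contents treated as missing (case-insensitive, stripped).
MISSING_TOKENS = frozenset({"", "na", "nan", "n/a", "null", "."})

TREATED, CONTROL = "treated", "control"
SURVIVOR, NON_SURVIVOR = "survivor", "non-survivor"
ANY = "any"

# heterogeneous source encodings normalized case-insensitively
DEFAULT_VALUE_MAP = {
    "treatment": {
        "treated": TREATED, "lps": TREATED, "lps-treated": TREATED,
        "septic": TREATED, "1": TREATED, "true": TREATED,
        "control": CONTROL, "sham": CONTROL, "non-septic": CONTROL,
        "0": CONTROL, "false": CONTROL,
    },
    "survival": {
        "survivor": SURVIVOR, "survived": SURVIVOR, "alive": SURVIVOR,
        "1": SURVIVOR, "true": SURVIVOR, "yes": SURVIVOR,
        "non-survivor": NON_SURVIVOR, "nonsurvivor": NON_SURVIVOR,
        "died": NON_SURVIVOR, "deceased": NON_SURVIVOR, "dead": NON_SURVIVOR,
        "0": NON_SURVIVOR, "false": NON_SURVIVOR, "no": NON_SURVIVOR,
    },
}

DEFAULT_COLUMNS = ("subject_id", "study", "treatment", "survival",
                   "time", "parameter", "value")


@dataclass(frozen=True)
class PopulationDef:
    """A subject subset defined by treatment and survival filters."""

    name: str
    treatment_filter: str  # treated | control | any
    survival_filter: str   # survivor | non-survivor | any

    def __post_init__(self):
        if self.treatment_filter not in (TREATED, CONTROL, ANY):
            raise ValueError(f"bad treatment filter {self.treatment_filter!r}")
        if self.survival_filter not in (SURVIVOR, NON_SURVIVOR, ANY):
            raise ValueError(f"bad survival filter {self.survival_filter!r}")

    def matches(self, treatment: str, survival: str) -> bool:
        return ((self.treatment_filter in (ANY, treatment))
                and (self.survival_filter in (ANY, survival)))


def canonical_populations() -> list[PopulationDef]:
    """The seven canonical populations, in order I–VII.

    I treated survivors, II treated non-survivors, III all treated,
    IV control survivors, V control non-survivors, VI all controls,
    VII everyone.  These are the {treated, control, any} ×
    {survivor, non-survivor, any} combinations minus the two strata
    that would pool both treatment arms within one survival outcome.
    """
    return [
        PopulationDef("I", TREATED, SURVIVOR),
        PopulationDef("II", TREATED, NON_SURVIVOR),
        PopulationDef("III", TREATED, ANY),
        PopulationDef("IV", CONTROL, SURVIVOR),
        PopulationDef("V", CONTROL, NON_SURVIVOR),
        PopulationDef("VI", CONTROL, ANY),
        PopulationDef("VII", ANY, ANY),
    ]


def population_by_name(name: str) -> PopulationDef:
    for pop in canonical_populations():
        if pop.name == name:
            return pop
    raise UnknownIdentifierError(f"unknown population {name!r}")


@dataclass(frozen=True)
class SubjectRecord:
    """One subject with its four group classifiers."""

    subject_id: str
    classifiers: dict

    def __post_init__(self):
        expected = {"G1_treatment", "G2_survival", "G3_id", "G4_study"}
        if set(self.classifiers) != expected:
            raise ValueError(f"classifiers must have keys {sorted(expected)}")
        if self.classifiers["G1_treatment"] not in (TREATED, CONTROL):
            raise ValueError("G1_treatment must be treated/control")
        if self.classifiers["G2_survival"] not in (SURVIVOR, NON_SURVIVOR):
            raise ValueError("G2_survival must be survivor/non-survivor")


@dataclass(frozen=True)
class CleanPair:
    """Two equal-length vectors over subjects valid for both parameters."""

    x_values: np.ndarray
    y_values: np.ndarray
    subject_ids: tuple[str, ...]
    x_parameter: str
    y_parameter: str
    time_point: int
    population: str

    @property
    def n(self) -> int:
        return int(self.x_values.size)

    def __post_init__(self):
        assert self.x_values.size == self.y_values.size == len(self.subject_ids)
        assert np.all(np.isfinite(self.x_values))
        assert np.all(np.isfinite(self.y_values))


class CrudeDatabase:
    """Long-format measurement pool with a declared parameter catalogue.

    Construct via :func:`load_database`, :func:`from_frames`, or the
    synthetic cohort generator.  Missing values are float NaN; at most
    one measurement exists per (subject, time, parameter).
    """

    def __init__(self, parameters, time_grid, subjects: pd.DataFrame,
                 measurements: pd.DataFrame):
        self.parameters = list(parameters)
        self.time_grid = [int(t) for t in time_grid]
        self._subjects = subjects          # index subject_id, sorted
        self._measurements = measurements  # subject_id, time, parameter, value
        self._wide: dict[int, pd.DataFrame] = {}

    # -- construction -------------------------------------------------
    @classmethod
    def from_frames(cls, parameters, time_grid, subjects: pd.DataFrame,
                    measurements: pd.DataFrame) -> "CrudeDatabase":
        parameters = list(parameters)
        time_grid = [int(t) for t in time_grid]
        subjects = subjects.sort_index()
        bad_t = set(measurements["time"]) - set(time_grid)
        if bad_t:
            raise IntegrityError(
                f"measurements at undeclared time points {sorted(bad_t)}; "
                f"declared grid is {time_grid}")
        bad_p = set(measurements["parameter"]) - set(parameters)
        if bad_p:
            raise IntegrityError(
                f"measurements for undeclared parameters {sorted(bad_p)[:5]}")
        unknown = set(measurements["subject_id"]) - set(subjects.index)
        if unknown:
            raise IntegrityError(
                f"measurements for unknown subjects {sorted(unknown)[:5]}")
        dup = measurements.duplicated(["subject_id", "time", "parameter"])
        if dup.any():
            first = measurements[dup].iloc[0]
            raise IntegrityError(
                "duplicate (subject, time, parameter) triple: "
                f"({first['subject_id']}, {first['time']}, "
                f"{first['parameter']})")
        return cls(parameters, time_grid, subjects,
                   measurements.reset_index(drop=True))

    # -- basic views --------------------------------------------------
    @property
    def subject_ids(self) -> list[str]:
        return list(self._subjects.index)

    @property
    def n_subjects(self) -> int:
        return len(self._subjects)

    @property
    def subjects(self) -> list[SubjectRecord]:
        return [
            SubjectRecord(sid, {
                "G1_treatment": row["treatment"],
                "G2_survival": row["survival"],
                "G3_id": sid,
                "G4_study": row["study"],
            })
            for sid, row in self._subjects.iterrows()
        ]

    @property
    def measurements(self) -> pd.DataFrame:
        return self._measurements.copy()

    def _wide_at(self, t: int) -> pd.DataFrame:
        """Subjects × parameters value table at time t (NaN = missing)."""
        if t not in self.time_grid:
            raise UnknownIdentifierError(
                f"time point {t} not in grid {self.time_grid}")
        if t not in self._wide:
            sl = self._measurements[self._measurements["time"] == t]
            wide = sl.pivot(index="subject_id", columns="parameter",
                            values="value")
            wide = wide.reindex(index=self._subjects.index,
                                columns=self.parameters)
            self._wide[t] = wide
        return self._wide[t]

    # -- population algebra -------------------------------------------
    def select_subjects(self, pop: PopulationDef) -> list[str]:
        """Subject ids satisfying both population filters, sorted."""
        sub = self._subjects
        mask = np.ones(len(sub), dtype=bool)
        if pop.treatment_filter != ANY:
            mask &= (sub["treatment"] == pop.treatment_filter).to_numpy()
        if pop.survival_filter != ANY:
            mask &= (sub["survival"] == pop.survival_filter).to_numpy()
        return list(sub.index[mask])

    # -- clean vectors -------------------------------------------------
    def extract_clean_pair(self, px: str, py: str, t: int,
                           pop: PopulationDef) -> CleanPair:
        """Paired vectors over population subjects valid for both px, py.

        Subjects appear in lexicographic id order, so repeated
        extractions (and hence fits and search keys) are reproducible.
        ``n`` may be 0.
        """
        for p in (px, py):
            if p not in self.parameters:
                raise UnknownIdentifierError(f"unknown parameter {p!r}")
        wide = self._wide_at(int(t))
        members = self.select_subjects(pop)
        sl = wide.loc[members, [px, py]] if px != py else wide.loc[members, [px]]
        if px == py:
            xv = sl[px].to_numpy(dtype=float)
            ok = np.isfinite(xv)
            ids = tuple(sl.index[ok])
            return CleanPair(xv[ok], xv[ok].copy(), ids, px, py, int(t),
                             pop.name)
        xv = sl[px].to_numpy(dtype=float)
        yv = sl[py].to_numpy(dtype=float)
        ok = np.isfinite(xv) & np.isfinite(yv)
        return CleanPair(xv[ok], yv[ok], tuple(sl.index[ok]), px, py,
                         int(t), pop.name)

    def sample_size_matrix(self, t: int, pop: PopulationDef) -> pd.DataFrame:
        """P×P matrix of pairwise-complete sample sizes at time t.

        Entry (i, j) is the number of population subjects with both Pi
        and Pj present; the diagonal counts subjects with Pi present.
        Symmetric by construction.
        """
        wide = self._wide_at(int(t))
        members = self.select_subjects(pop)
        present = wide.loc[members].notna().to_numpy()
        counts = present.T.astype(np.int64) @ present.astype(np.int64)
        return pd.DataFrame(counts, index=self.parameters,
                            columns=self.parameters)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"CrudeDatabase({len(self.parameters)} parameters, "
                f"{self.n_subjects} subjects, "
                f"{len(self._measurements)} measurements, "
                f"time grid {self.time_grid})")


def _normalize_classifier(series: pd.Series, kind: str,
                          value_map: dict) -> pd.Series:
    mapping = value_map[kind]
    norm = series.astype(str).str.strip().str.lower().map(mapping)
    bad = norm.isna()
    if bad.any():
        raise SchemaError(
            f"unrecognized {kind} value(s) "
            f"{sorted(set(series[bad].astype(str)))[:5]}; extend the value "
            "map if your encoding is not covered")
    return norm


def load_database(path, schema: dict | None = None,
                  time_grid=DEFAULT_TIME_GRID,
                  missing_tokens=MISSING_TOKENS,
                  value_map: dict | None = None) -> CrudeDatabase:
    """Read a long-format CSV/TSV into a validated :class:`CrudeDatabase`.

    Expected columns (remappable via ``schema``, a map from the
    canonical names to the file's names): subject_id, study, treatment,
    survival, time, parameter, value.  Unparseable numeric cells and
    ``missing_tokens`` become missing values (the count is logged);
    duplicated (subject, time, parameter) rows and rows at undeclared
    time points are errors, as are subjects with missing or
    inconsistent classifiers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    schema = schema or {}
    colmap = {schema.get(c, c): c for c in DEFAULT_COLUMNS}
    missing_cols = [src for src in colmap if src not in raw.columns]
    if missing_cols:
        raise SchemaError(
            f"required column(s) {missing_cols} not found in {path.name}; "
            f"available: {list(raw.columns)}")
    df = raw[list(colmap)].rename(columns=colmap)

    value_map = value_map or DEFAULT_VALUE_MAP
    df["treatment"] = _normalize_classifier(df["treatment"], "treatment",
                                            value_map)
    df["survival"] = _normalize_classifier(df["survival"], "survival",
                                           value_map)
    try:
        df["time"] = df["time"].astype(int)
    except ValueError as exc:
        raise SchemaError(f"non-integer time value: {exc}") from exc

    tokens = {t.lower() for t in missing_tokens}
    stripped = df["value"].str.strip()
    is_token = stripped.str.lower().isin(tokens)
    values = pd.to_numeric(stripped.where(~is_token, other=""),
                           errors="coerce")
    unparseable = int((values.isna() & ~is_token).sum())
    if unparseable:
        logger.warning("%d unparseable numeric cell(s) in %s treated as "
                       "missing", unparseable, path.name)
    df["value"] = values

    # classifier consistency: one (treatment, survival, study) per subject
    cls = df.groupby("subject_id")[["treatment", "survival", "study"]]
    if (cls.nunique() > 1).any().any():
        bad = cls.nunique()
        bad = bad[(bad > 1).any(axis=1)].index[0]
        raise IntegrityError(
            f"subject {bad!r} has inconsistent classifier values")
    subjects = (df.groupby("subject_id")[["treatment", "survival", "study"]]
                .first())

    parameters = sorted(df["parameter"].unique(),
                        key=_parameter_sort_key)
    measurements = df[["subject_id", "time", "parameter", "value"]]
    db = CrudeDatabase.from_frames(parameters, time_grid, subjects,
                                   measurements)
    logger.info("loaded %s", db)
    return db


def _parameter_sort_key(p: str):
    """Sort P2 before P10 when ids follow the P<number> convention."""
    if len(p) > 1 and p[0] in "Pp" and p[1:].isdigit():
        return (0, int(p[1:]), p)
    return (1, 0, p)


def write_database(db: CrudeDatabase, path) -> None:
    """Write the long-format TSV that :func:`load_database` reads back."""
    path = Path(path)
    sub = db._subjects
    m = db._measurements.copy()
    m["study"] = m["subject_id"].map(sub["study"])
    m["treatment"] = m["subject_id"].map(sub["treatment"])
    m["survival"] = m["subject_id"].map(sub["survival"])
    m = m[list(DEFAULT_COLUMNS)]
    m = m.sort_values(["subject_id", "time", "parameter"],
                      kind="stable")
    m.to_csv(path, sep="\t", index=False, na_rep="NA")
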