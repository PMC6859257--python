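"""Study-shaped synthetic cohorts with planted pairwise relationships.

The generator emulates the *structure* of a pooled longitudinal rat
endotoxemia database — two treatment arms, binary survival, several
contributing studies, a fixed time grid, dozens of numeric parameters,
missingness — without attempting to mimic the physiology behind any
parameter name.  Unplanted parameters are independent Gaussian noise
with per-parameter location and scale; a planted relation makes one
parameter a prototype function of another, plus additive Gaussian
noise, only for subjects in its active populations and time points.
Ground truth travels with the cohort, so screens can be scored for
sensitivity, family identification and false positives.

Cohort defaults mirror the study shape this engine was built around:
63 treated and 57 control subjects, 45 parameters, six time points
(0–300 min), 11 studies.  Survival rates are generator choices —
treated arms of endotoxemia models lose roughly half the animals,
control deaths are rare.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (CONTROL, DEFAULT_TIME_GRID, NON_SURVIVOR, SURVIVOR,
                         TREATED, CrudeDatabase, population_by_name)
from .prototypes import evaluate, get_prototype
from .screening import ScreenResult

__all__ = [
    "CohortSpec", "PlantedRelation", "generate_cohort", "write_cohort",
    "load_truth", "truth_confusion", "default_planted_params",
]


@dataclass(frozen=True)
class CohortSpec:
    """Shape of a synthetic cohort."""

    n_treated: int = 63
    n_control: int = 57
    survival_rate_treated: float = 0.55
    survival_rate_control: float = 0.97
    n_parameters: int = 45
    time_grid: tuple[int, ...] = DEFAULT_TIME_GRID
    n_studies: int = 11
    missing_rate: float = 0.0
    rng_seed: int = 1
    x_range: tuple[float, float] = (0.0, 10.0)

    def __post_init__(self):
        for r in (self.survival_rate_treated, self.survival_rate_control,
                  self.missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if min(self.n_treated, self.n_control, self.n_parameters,
               self.n_studies) < 0:
            raise ValueError("counts must be >= 0")


@dataclass(frozen=True)
class PlantedRelation:
    """Ground truth: py = f(px) + noise in the given populations/times.

    ``noise_sd`` is a fraction of the planted curve's response range
    over the x sampling window, so 0.01 means 1 % noise regardless of
    the family's natural scale.
    """

    x_parameter: str
    y_parameter: str
    prototype: str
    params: tuple[float, ...]
    populations: tuple[str, ...] = ("VII",)
    time_points: tuple[int, ...] | None = None  # None = all grid times
    noise_sd: float = 0.0

    def __post_init__(self):
        proto = get_prototype(self.prototype)
        if len(self.params) != proto.arity:
            raise ValueError(
                f"{self.prototype} needs {proto.arity} parameters")
        if not self.populations:
            raise ValueError("active population set must be non-empty")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


#: Planted parameter vectors whose curves show each family's signature
#: shape over the default x window (0, 10): the sigmoid inflects inside
#: the window, the exponential and logarithm curve strongly, the cubic
#: has two interior turning points.  Chosen once for identifiability.
_DEFAULT_PLANTED = {
    "linear": (2.0, 1.0),
    "sigmoid": (1.0, 9.0, 4.0, 0.15, 5.0),
    "exponential": (0.5, 0.55, 0.0, 2.0),
    "quadratic": (1.0, -8.0, 18.0),
    "cubic": (0.2, -3.0, 12.0, 1.0),
    "logarithmic": (1.0, 2.0, 0.3, 0.0),
}


def default_planted_params(prototype: str) -> tuple[float, ...]:
    """A curve with the family's signature shape on the default x window."""
    return _DEFAULT_PLANTED[prototype]


def _curve_range(relation: PlantedRelation, spec: CohortSpec) -> float:
    xg = np.linspace(spec.x_range[0], spec.x_range[1], 256)
    proto = get_prototype(relation.prototype)
    f = evaluate(proto, np.asarray(relation.params, float), xg)
    if f is None:
        raise ValueError(
            f"planted {relation.prototype} curve infeasible on x_range")
    return float(f.max() - f.min())


def generate_cohort(spec: CohortSpec,
                    relations=()) -> tuple[CrudeDatabase, dict]:
    """Generate a cohort and its ground-truth record.

    Fully determined by ``spec.rng_seed``: subjects get treatment arm,
    survival and study; every parameter gets independent noise; planted
    relations overwrite the y-parameter for subjects of the active
    populations at the active times; missingness is applied completely
    at random at ``missing_rate``.
    """
    relations = list(relations)
    parameters = [f"P{i + 1}" for i in range(spec.n_parameters)]
    declared = set(parameters)
    times = [int(t) for t in spec.time_grid]
    for rel in relations:
        for p in (rel.x_parameter, rel.y_parameter):
            if p not in declared:
                raise ValueError(f"planted relation references undeclared "
                                 f"parameter {p!r}")
        for t in (rel.time_points or times):
            if int(t) not in times:
                raise ValueError(f"planted relation references undeclared "
                                 f"time point {t}")
        for pop in rel.populations:
            population_by_name(pop)  # raises if unknown

    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_treated + spec.n_control
    width = max(3, len(str(max(n, 1))))
    subject_ids = [f"S{i + 1:0{width}d}" for i in range(n)]
    treatment = np.array([TREATED] * spec.n_treated
                         + [CONTROL] * spec.n_control)
    surv_p = np.where(treatment == TREATED, spec.survival_rate_treated,
                      spec.survival_rate_control)
    survival = np.where(rng.random(n) < surv_p, SURVIVOR, NON_SURVIVOR)
    study = np.array([f"ST{(i % spec.n_studies) + 1:02d}" for i in range(n)]) \
        if spec.n_studies else np.array(["ST01"] * n)
    subjects = pd.DataFrame({"treatment": treatment, "survival": survival,
                             "study": study}, index=pd.Index(
                                 subject_ids, name="subject_id"))

    T, P = len(times), len(parameters)
    # independent baseline noise; per-parameter location and scale
    mu = rng.uniform(10.0, 100.0, P)
    sd = rng.uniform(1.0, 10.0, P)
    values = rng.normal(mu[None, None, :], sd[None, None, :], (n, T, P))

    pidx = {p: i for i, p in enumerate(parameters)}
    tidx = {t: i for i, t in enumerate(times)}
    # x-parameters of planted pairs are uniform over the declared window
    # for everyone, so the relation is identifiable wherever it is active
    for rel in relations:
        xi = pidx[rel.x_parameter]
        values[:, :, xi] = rng.uniform(spec.x_range[0], spec.x_range[1],
                                       (n, T))
    for rel in relations:
        xi, yi = pidx[rel.x_parameter], pidx[rel.y_parameter]
        proto = get_prototype(rel.prototype)
        yrange = _curve_range(rel, spec)
        active_subject = np.zeros(n, dtype=bool)
        for pop_name in rel.populations:
            pop = population_by_name(pop_name)
            active_subject |= np.array([
                pop.matches(tr, sv) for tr, sv in zip(treatment, survival)])
        active_times = [tidx[int(t)] for t in (rel.time_points or times)]
        for ti in active_times:
            xs = values[active_subject, ti, xi]
            f = evaluate(proto, np.asarray(rel.params, float), xs)
            if f is None:
                raise ValueError(
                    f"planted {rel.prototype} curve infeasible at "
                    f"sampled x values")
            noise = (rng.normal(0.0, rel.noise_sd * yrange, xs.size)
                     if rel.noise_sd > 0 else 0.0)
            values[active_subject, ti, yi] = f + noise

    if spec.missing_rate > 0:
        missing = rng.random((n, T, P)) < spec.missing_rate
        values = np.where(missing, np.nan, values)

    long = pd.DataFrame({
        "subject_id": np.repeat(subject_ids, T * P),
        "time": np.tile(np.repeat(times, P), n),
        "parameter": np.tile(parameters, n * T),
        "value": values.reshape(-1),
    })
    db = CrudeDatabase.from_frames(parameters, times, subjects, long)

    truth = {
        "spec": {**asdict(spec),
                 "time_grid": list(spec.time_grid),
                 "x_range": list(spec.x_range)},
        "relations": [
            {**asdict(rel),
             "params": list(rel.params),
             "populations": list(rel.populations),
             "time_points": (list(rel.time_points)
                             if rel.time_points is not None else None)}
            for rel in relations
        ],
    }
    return db, truth


def write_cohort(db: CrudeDatabase, truth: dict, out_dir) -> tuple[Path, Path]:
    """Write the long-format TSV plus the ground-truth JSON."""
    from .data_model import write_database

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data_path = out_dir / "cohort.tsv"
    truth_path = out_dir / "truth.json"
    write_database(db, data_path)
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True))
    return data_path, truth_path


def load_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def truth_confusion(screen: ScreenResult, truth: dict,
                    filter_spec) -> dict:
    """Score a screen against the cohort's ground truth.

    A planted relation is *detected* in one of its active
    (time, population) slices present in the screen if its (px, py)
    cell — either orientation — survives the filter in the best matrix;
    it is *family-correct* if the winning prototype at the planted
    orientation is the planted family.  Every unplanted, non-self
    unordered cell that survives the filter counts as a false positive.
    Returns per-relation rows plus aggregate sensitivity and
    false-positive rate.
    """
    from .postprocessing import filter_results

    best = screen.best_results
    survivors = filter_results(best, filter_spec)
    surviving_cells = {
        (row.time_point, row.population,
         frozenset((row.x_parameter, row.y_parameter)))
        for row in survivors.itertuples()
    }

    grid_times = set(screen.grid.time_points)
    grid_pops = {pop.name for pop in screen.grid.populations}
    all_times = [int(t) for t in truth["spec"]["time_grid"]]

    rows = []
    planted_cells = set()
    for rel in truth["relations"]:
        times = [int(t) for t in (rel["time_points"] or all_times)]
        for t in times:
            if t not in grid_times:
                continue
            for pop in rel["populations"]:
                if pop not in grid_pops:
                    continue
                cell = frozenset((rel["x_parameter"], rel["y_parameter"]))
                planted_cells.add((t, pop, cell))
                detected = (t, pop, cell) in surviving_cells
                sub = best[(best.time_point == t)
                           & (best.population == pop)
                           & (best.x_parameter == rel["x_parameter"])
                           & (best.y_parameter == rel["y_parameter"])]
                won = sub.iloc[0]["prototype"] if len(sub) else None
                rows.append({
                    "x_parameter": rel["x_parameter"],
                    "y_parameter": rel["y_parameter"],
                    "time_point": t, "population": pop,
                    "prototype": rel["prototype"],
                    "detected": bool(detected),
                    "best_prototype": won,
                    "prototype_correct": won == rel["prototype"],
                })

    false_cells = surviving_cells - planted_cells
    # candidate universe: unordered non-self cells per screened slice
    p = len(screen.grid.parameters)
    n_unordered = p * (p - 1) // 2
    n_slices = len(screen.grid.time_points) * len(screen.grid.populations)
    n_candidates = n_unordered * n_slices - len(planted_cells)
    table = pd.DataFrame(rows)
    return {
        "relations": table,
        "sensitivity": (float(table["detected"].mean())
                        if len(table) else float("nan")),
        "family_accuracy": (float(table["prototype_correct"].mean())
                            if len(table) else float("nan")),
        "n_false_positives": len(false_cells),
        "false_positive_rate": (len(false_cells) / n_candidates
                                if n_candidates else float("nan")),
    }
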