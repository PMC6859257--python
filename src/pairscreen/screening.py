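"""All-pairs screening: enumerate, fit, select and assemble matrices.

One *task* is (x-parameter, y-parameter, time point, population,
prototype).  The full grid over P parameters, T time points, Q
populations and R prototypes has P²·T·Q·R tasks — ordered pairs and
self-pairs included, which is what makes a 45-parameter study grid
count 2025 combinations per slice and 510 300 tasks overall.  Every
fitted optimum carries a unique, parseable search key so any matrix
cell can be traced back to its task.

The screen fills one goodness-of-fit matrix per (time, population,
prototype) slice plus a "best" matrix per (time, population) holding,
for each cell, the best-fitting family after a parsimony-aware
tie-break.  Self-pairs are fitted (they are part of the printed counts)
but flagged trivial in the long results table so candidate lists can
drop them.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import CrudeDatabase, PopulationDef
from .errors import KeyParseError, UnfittableError, UnknownIdentifierError
from .fitting import FitConfig, FitResult, fit_batch
from .prototypes import PrototypeSpec, list_prototypes

logger = logging.getLogger(__name__)

__all__ = [
    "TaskGrid", "GofMatrix", "ScreenResult", "enumerate_tasks",
    "make_search_key", "parse_search_key", "select_best", "run_screen",
]

#: gof margin within which two prototypes count as tied (parsimony rule)
DEFAULT_TIE_TOLERANCE = 1e-3

BEST = "best"

_CANONICAL_INDEX = {p.name: i for i, p in enumerate(list_prototypes())}


@dataclass(frozen=True)
class TaskGrid:
    """The cartesian grid of regression tasks to execute."""

    parameters: tuple[str, ...]
    time_points: tuple[int, ...]
    populations: tuple[PopulationDef, ...]
    prototypes: tuple[PrototypeSpec, ...]

    @classmethod
    def build(cls, parameters, time_points, populations, prototypes):
        return cls(tuple(parameters), tuple(int(t) for t in time_points),
                   tuple(populations), tuple(prototypes))

    @property
    def task_count(self) -> int:
        return (len(self.parameters) ** 2 * len(self.time_points)
                * len(self.populations) * len(self.prototypes))


def enumerate_tasks(grid: TaskGrid):
    """Yield every (px, py, t, pop, proto) exactly once, deterministically.

    Order: time-major, then population, then x-parameter, y-parameter,
    and canonical prototype order innermost.
    """
    for t in grid.time_points:
        for pop in grid.populations:
            for px in grid.parameters:
                for py in grid.parameters:
                    for proto in grid.prototypes:
                        yield (px, py, t, pop, proto)


def make_search_key(px: str, py: str, t: int, pop: str, proto: str) -> str:
    """Unique, stable key ``<px>~<py>@t<t>|<pop>|<proto>`` for one task."""
    return f"{px}~{py}@t{t}|{pop}|{proto}"


_KEY_RE = re.compile(
    r"^(?P<px>[^~@|]+)~(?P<py>[^~@|]+)@t(?P<t>-?\d+)"
    r"\|(?P<pop>[^|]+)\|(?P<proto>[^|]+)$")


def parse_search_key(key: str) -> tuple[str, str, int, str, str]:
    """Inverse of :func:`make_search_key`; raises on malformed keys."""
    m = _KEY_RE.match(key)
    if not m:
        raise KeyParseError(
            f"malformed search key {key!r}; expected "
            "'<px>~<py>@t<time>|<population>|<prototype>'")
    return (m["px"], m["py"], int(m["t"]), m["pop"], m["proto"])


def select_best(fits: dict[str, FitResult],
                tie_tolerance: float = DEFAULT_TIE_TOLERANCE):
    """Pick the best-fitting prototype for one cell.

    Maximal gof wins; prototypes whose gof is within ``tie_tolerance``
    of the maximum count as tied, and ties resolve to the fewest free
    parameters, then canonical order.  Without the tolerance a nested
    family (cubic ⊇ linear) would beat the true family by a noise-level
    margin on every noisy cell.  Returns (name, FitResult) or None if
    nothing is defined.
    """
    defined = {name: r for name, r in fits.items()
               if r is not None and np.isfinite(r.gof)}
    if not defined:
        return None
    top = max(r.gof for r in defined.values())
    tied = [(len(r.params), _CANONICAL_INDEX[name], name, r)
            for name, r in defined.items() if r.gof >= top - tie_tolerance]
    tied.sort(key=lambda item: (item[0], item[1]))
    _, _, name, result = tied[0]
    return name, result


@dataclass
class GofMatrix:
    """P×P fit-quality matrices for one (time, population, prototype) slice.

    ``prototype`` may be a family name or ``"best"``.  Undefined cells
    (skipped tasks) are NaN in ``gof_values`` and written as "NA".  For
    the best slice, ``proto_values`` names the winning family per cell.
    """

    axis: tuple[str, ...]
    time_point: int
    population: str
    prototype: str
    gof_values: np.ndarray
    n_values: np.ndarray
    key_values: np.ndarray
    proto_values: np.ndarray | None = None
    corr_values: np.ndarray | None = None  # signed Pearson, linear slice only

    def to_frame(self, which: str = "gof") -> pd.DataFrame:
        data = {"gof": self.gof_values, "n": self.n_values,
                "key": self.key_values, "proto": self.proto_values,
                "corr": self.corr_values}[which]
        if data is None:
            raise ValueError(f"matrix has no {which!r} layer")
        return pd.DataFrame(data, index=list(self.axis),
                            columns=list(self.axis))

    def write_tsv(self, path) -> None:
        df = self.to_frame("gof").copy()
        df.index.name = "parameter"
        df.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")


@dataclass
class ScreenResult:
    """Everything one screen run produced."""

    grid: TaskGrid
    matrices: dict  # (t, pop_name, proto_name_or_best) -> GofMatrix
    results: pd.DataFrame       # one row per (cell, prototype) task
    best_results: pd.DataFrame  # one row per cell, winning family
    n_fitted: int
    n_skipped: int
    skip_reasons: dict

    def matrix(self, t: int, pop: str, proto: str = BEST) -> GofMatrix:
        try:
            return self.matrices[(int(t), pop, proto)]
        except KeyError:
            raise UnknownIdentifierError(
                f"no matrix for (t={t}, pop={pop}, proto={proto})") from None


_RESULT_COLUMNS = [
    "search_key", "x_parameter", "y_parameter", "time_point", "population",
    "prototype", "n", "gof", "sse_ratio", "converged", "self_pair",
    "pearson", "skip_reason", "params",
]


def _result_row(px, py, t, pop_name, proto_name, key, n, res,
                skip_reason=None):
    gof = sse = np.nan
    converged = False
    pearson = np.nan
    params = ""
    if res is not None:
        gof, sse, converged = res.gof, res.sse_ratio, res.converged
        params = ";".join(f"{v:.12g}" for v in res.params)
        if proto_name == "linear" and np.isfinite(gof) and gof >= 0:
            pearson = float(np.sign(res.params[0]) * np.sqrt(gof))
    return {
        "search_key": key, "x_parameter": px, "y_parameter": py,
        "time_point": t, "population": pop_name, "prototype": proto_name,
        "n": n, "gof": gof, "sse_ratio": sse, "converged": converged,
        "self_pair": px == py, "pearson": pearson,
        "skip_reason": skip_reason or "", "params": params,
    }


def run_screen(db: CrudeDatabase, grid: TaskGrid,
               cfg: FitConfig | None = None, out_dir=None,
               tie_tolerance: float = DEFAULT_TIE_TOLERANCE,
               resume: bool = True) -> ScreenResult:
    """Execute every task of ``grid`` against ``db``.

    For each (time, population) slice the clean pairs of all P² cells
    are extracted once and each prototype is fitted across the whole
    slice in a single vectorized multistart sweep.  Unfittable cells
    are recorded with a machine-readable reason (``n_too_small``,
    ``sst_zero``, ``degenerate_x``) rather than failing the run, so
    fitted + skipped always equals the grid's task count.

    If ``out_dir`` is given, one gof TSV per slice plus the long
    results table are written there incrementally after each
    (time, population) slice; a rerun with ``resume=True`` reloads
    finished slices from the results table by search key instead of
    refitting them.  The run is deterministic: same db + grid + cfg
    gives byte-identical outputs.
    """
    cfg = cfg or FitConfig()
    unknown_p = set(grid.parameters) - set(db.parameters)
    if unknown_p:
        raise UnknownIdentifierError(
            f"grid parameters not in database: {sorted(unknown_p)}")
    unknown_t = set(grid.time_points) - set(db.time_grid)
    if unknown_t:
        raise UnknownIdentifierError(
            f"grid time points not in database: {sorted(unknown_t)}")

    out_dir = Path(out_dir) if out_dir is not None else None
    prior: dict[str, dict] = {}
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        results_path = out_dir / "results.tsv"
        if resume and results_path.exists():
            old = pd.read_csv(results_path, sep="\t", keep_default_na=False,
                              na_values=["NA"], dtype={"skip_reason": str,
                                                       "params": str})
            prior = {row["search_key"]: row.to_dict()
                     for _, row in old.iterrows()}
            logger.info("resuming: %d prior task results", len(prior))

    P = len(grid.parameters)
    axis = grid.parameters
    matrices: dict = {}
    rows: list[dict] = []
    best_rows: list[dict] = []
    n_fitted = 0
    skip_reasons: dict[str, int] = {}

    for t in grid.time_points:
        for pop in grid.populations:
            cells = [(px, py) for px in axis for py in axis]
            pairs = [db.extract_clean_pair(px, py, t, pop)
                     for px, py in cells]
            per_proto: dict[str, list] = {}
            for proto in grid.prototypes:
                keys = [make_search_key(px, py, t, pop.name, proto.name)
                        for px, py in cells]
                if prior and all(k in prior for k in keys):
                    fits = [_rehydrate(prior[k], proto, pairs[i])
                            for i, k in enumerate(keys)]
                else:
                    fits = fit_batch(proto, pairs, cfg, search_keys=keys)
                per_proto[proto.name] = fits

                gof = np.full((P, P), np.nan)
                nmat = np.zeros((P, P), dtype=np.int64)
                kmat = np.empty((P, P), dtype=object)
                corr = np.full((P, P), np.nan) if proto.name == "linear" \
                    else None
                for idx, (px, py) in enumerate(cells):
                    i, j = divmod(idx, P)
                    kmat[i, j] = keys[idx]
                    nmat[i, j] = pairs[idx].n
                    r = fits[idx]
                    if isinstance(r, UnfittableError):
                        reason = r.reason
                        skip_reasons[reason] = skip_reasons.get(reason, 0) + 1
                        rows.append(_result_row(
                            px, py, t, pop.name, proto.name, keys[idx],
                            pairs[idx].n, None, skip_reason=reason))
                        continue
                    n_fitted += 1
                    if np.isfinite(r.gof):
                        gof[i, j] = r.gof
                        if corr is not None and r.gof >= 0:
                            corr[i, j] = (np.sign(r.params[0])
                                          * np.sqrt(r.gof))
                    rows.append(_result_row(px, py, t, pop.name, proto.name,
                                            keys[idx], pairs[idx].n, r))
                matrices[(t, pop.name, proto.name)] = GofMatrix(
                    axis, t, pop.name, proto.name, gof, nmat, kmat,
                    corr_values=corr)

            # best slice
            bgof = np.full((P, P), np.nan)
            bn = np.zeros((P, P), dtype=np.int64)
            bkey = np.empty((P, P), dtype=object)
            bproto = np.empty((P, P), dtype=object)
            for idx, (px, py) in enumerate(cells):
                i, j = divmod(idx, P)
                bn[i, j] = pairs[idx].n
                fits = {name: (r if not isinstance(r, UnfittableError)
                               else None)
                        for name, r in
                        ((pr.name, per_proto[pr.name][idx])
                         for pr in grid.prototypes)}
                choice = select_best(fits, tie_tolerance)
                bkey[i, j] = make_search_key(px, py, t, pop.name, BEST)
                if choice is None:
                    bproto[i, j] = ""
                    continue
                name, r = choice
                bgof[i, j] = r.gof if np.isfinite(r.gof) else np.nan
                bproto[i, j] = name
                best_rows.append(_result_row(px, py, t, pop.name, name,
                                             r.search_key, pairs[idx].n, r))
            matrices[(t, pop.name, BEST)] = GofMatrix(
                axis, t, pop.name, BEST, bgof, bn, bkey, proto_values=bproto)

            if out_dir is not None:
                _write_outputs(out_dir, matrices, rows, best_rows, t,
                               pop.name, grid)
            logger.info("slice t=%d pop=%s done (%d tasks fitted so far)",
                        t, pop.name, n_fitted)

    results = pd.DataFrame(rows, columns=_RESULT_COLUMNS)
    best_results = pd.DataFrame(best_rows, columns=_RESULT_COLUMNS)
    n_skipped = int(sum(skip_reasons.values()))
    screen = ScreenResult(grid, matrices, results, best_results,
                          n_fitted, n_skipped, skip_reasons)
    if out_dir is not None:
        results.to_csv(out_dir / "results.tsv", sep="\t", index=False,
                       na_rep="NA", float_format="%.12g")
        best_results.to_csv(out_dir / "best_results.tsv", sep="\t",
                            index=False, na_rep="NA", float_format="%.12g")
    logger.info("screen complete: %d fitted, %d skipped %s of %d tasks",
                n_fitted, n_skipped, skip_reasons, grid.task_count)
    return screen


def _rehydrate(row: dict, proto: PrototypeSpec, pair):
    """Rebuild a FitResult (or skip signal) from a persisted results row."""
    reason = str(row.get("skip_reason") or "").strip()
    if reason:
        return UnfittableError(reason)
    params = tuple(float(v) for v in str(row["params"]).split(";"))
    sse = float(row["sse_ratio"])
    converged = str(row["converged"]).strip().lower() in ("true", "1")
    return FitResult(
        prototype=proto.name, params=params, sse_ratio=sse,
        gof=1.0 - sse if np.isfinite(sse) else float("-inf"),
        n=int(row["n"]), converged=converged,
        n_starts_used=0, search_key=row["search_key"])


def _write_outputs(out_dir: Path, matrices, rows, best_rows, t, pop_name,
                   grid) -> None:
    for proto in list(grid.prototypes) + [None]:
        name = proto.name if proto is not None else BEST
        key = (t, pop_name, name)
        if key in matrices:
            fname = f"gof_t{t}_pop{pop_name}_{name}.tsv"
            matrices[key].write_tsv(out_dir / fname)
    pd.DataFrame(rows, columns=_RESULT_COLUMNS).to_csv(
        out_dir / "results.tsv", sep="\t", index=False, na_rep="NA",
        float_format="%.12g")
    pd.DataFrame(best_rows, columns=_RESULT_COLUMNS).to_csv(
        out_dir / "best_results.tsv", sep="\t", index=False, na_rep="NA",
        float_format="%.12g")
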