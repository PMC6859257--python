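"""Discovery strategies over screened goodness-of-fit matrices.

After the screen, candidate prognostic markers are surfaced by a few
deliberately simple strategies:

* threshold filtering (gof ≥ 0.7, n ≥ 12 by default) to drop nonsense
  and under-powered cells;
* population-difference matrices — which pairs couple differently in
  survivors and non-survivors;
* per-pair gof time courses and a max−min change score — which pairs
  gain or lose coupling as disease progresses — with a coarse
  early/late/lockstep labelling;
* greedy matrix seriation to make parameter clusters visually
  contiguous;
* an exploratory permutation test attaching an empirical p-value to a
  single pair (no multiplicity correction is attempted across the
  ~10⁵ cells of a full screen; the p-values are labelled exploratory).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CleanPair
from .errors import DegenerateTargetError, UnfittableError
from .fitting import FitConfig, fit
from .prototypes import list_prototypes
from .screening import GofMatrix, make_search_key, select_best

__all__ = [
    "FilterSpec", "filter_results", "population_difference",
    "rank_differences", "time_course", "rank_by_change",
    "classify_marker_timing", "permutation_significance", "seriate_matrix",
]


@dataclass(frozen=True)
class FilterSpec:
    """Candidate filter: minimum sample size and goodness of fit."""

    min_n: int = 12
    min_gof: float = 0.7
    exclude_self_pairs: bool = True
    dedupe_orientation: bool = True

    def __post_init__(self):
        if self.min_n < 1:
            raise ValueError("min_n must be >= 1")
        if self.min_gof > 1:
            raise ValueError("min_gof cannot exceed 1")


def filter_results(results: pd.DataFrame, spec: FilterSpec) -> pd.DataFrame:
    """Keep rows meeting n ≥ min_n and gof ≥ min_gof.

    Self-pairs are dropped when ``exclude_self_pairs``; with
    ``dedupe_orientation`` only the better-fitting orientation of each
    unordered pair within a (time, population) slice is kept, ties
    resolved toward the catalogue orientation (x before y).  Idempotent
    and always a subset of its input.
    """
    df = results.copy()
    keep = (df["n"] >= spec.min_n) & (df["gof"] >= spec.min_gof)
    df = df[keep.fillna(False)]
    if spec.exclude_self_pairs:
        df = df[df["x_parameter"] != df["y_parameter"]]
    if spec.dedupe_orientation and len(df):
        pair_key = df.apply(
            lambda r: (r["time_point"], r["population"],
                       *sorted((r["x_parameter"], r["y_parameter"]))),
            axis=1)
        forward = df["x_parameter"] == pair_key.map(lambda k: k[2])
        df = (df.assign(_pair=pair_key, _fw=forward)
                .sort_values(["gof", "_fw"], ascending=[False, False],
                             kind="stable")
                .drop_duplicates("_pair", keep="first")
                .drop(columns=["_pair", "_fw"]))
        df = df.sort_index()
    return df


def population_difference(m_a: GofMatrix, m_b: GofMatrix) -> pd.DataFrame:
    """Entry-wise gof difference A − B between two population slices.

    Undefined where either operand is undefined.  Antisymmetric under
    operand swap.  Rank the absolute values (see
    :func:`rank_differences`) to ask which pairs behave most
    differently between the two populations.
    """
    if tuple(m_a.axis) != tuple(m_b.axis):
        raise ValueError("matrices have different parameter axes")
    if m_a.time_point != m_b.time_point:
        raise ValueError("matrices are from different time points")
    if m_a.prototype != m_b.prototype:
        raise ValueError("matrices select different prototypes "
                         f"({m_a.prototype!r} vs {m_b.prototype!r})")
    diff = m_a.gof_values - m_b.gof_values
    return pd.DataFrame(diff, index=list(m_a.axis), columns=list(m_a.axis))


def rank_differences(diff: pd.DataFrame,
                     include_self: bool = False) -> pd.DataFrame:
    """Cells of a difference matrix ranked by |difference|, descending.

    Keeps one orientation per unordered pair; ties break on the cell
    name so the ranking is stable.
    """
    rows = []
    params = list(diff.index)
    for i, px in enumerate(params):
        for j, py in enumerate(params):
            if j < i or (i == j and not include_self):
                continue
            d = diff.iat[i, j]
            if np.isfinite(d):
                rows.append({"x_parameter": px, "y_parameter": py,
                             "difference": float(d),
                             "abs_difference": abs(float(d))})
    out = pd.DataFrame(rows, columns=["x_parameter", "y_parameter",
                                      "difference", "abs_difference"])
    return out.sort_values(["abs_difference", "x_parameter", "y_parameter"],
                           ascending=[False, True, True],
                           kind="stable").reset_index(drop=True)


def time_course(best_results: pd.DataFrame, px: str, py: str, pop: str,
                time_points) -> np.ndarray:
    """Best-fit gof profile of one cell across the time grid.

    Returns one value per requested time point, NaN where the cell has
    no defined best fit.
    """
    sub = best_results[(best_results.x_parameter == px)
                       & (best_results.y_parameter == py)
                       & (best_results.population == pop)]
    by_t = dict(zip(sub.time_point, sub.gof))
    return np.array([by_t.get(int(t), np.nan) for t in time_points])


def rank_by_change(profiles: dict, min_defined: int = 2) -> pd.DataFrame:
    """Rank cells by how much their gof profile changes over time.

    ``profiles`` maps a label (e.g. a search key or (px, py) tuple) to
    a gof profile array.  The change score is max − min over defined
    entries — it answers "which pairs changed the most over time"
    and is unaffected by permuting the time axis.  Cells with fewer
    than ``min_defined`` defined entries are excluded; descending
    score, ties broken by label.
    """
    if min_defined < 2:
        raise ValueError("min_defined must be >= 2")
    rows = []
    for label, prof in profiles.items():
        prof = np.asarray(prof, dtype=float)
        defined = prof[np.isfinite(prof)]
        if defined.size < min_defined:
            continue
        rows.append({"cell": label,
                     "score": float(defined.max() - defined.min()),
                     "n_defined": int(defined.size)})
    out = pd.DataFrame(rows, columns=["cell", "score", "n_defined"])
    out["_label"] = out["cell"].astype(str)
    out = (out.sort_values(["score", "_label"], ascending=[False, True],
                           kind="stable")
           .drop(columns="_label").reset_index(drop=True))
    return out


def classify_marker_timing(profile, high: float = 0.7,
                           low: float = 0.3) -> str:
    """Label a gof time course as lockstep, early, late or other.

    lockstep: coupled at every defined time point (all ≥ high) — the
    bicarbonate/base-excess archetype.  early: starts coupled, ends
    decoupled (first ≥ high, last ≤ low).  late: starts decoupled, ends
    coupled.  Anything else: other.
    """
    if low >= high:
        raise ValueError("low threshold must be below high")
    prof = np.asarray(profile, dtype=float)
    defined = prof[np.isfinite(prof)]
    if defined.size < 2:
        raise ValueError("profile needs at least 2 defined entries")
    if np.all(defined >= high):
        return "lockstep"
    if defined[0] >= high and defined[-1] <= low:
        return "early"
    if defined[0] <= low and defined[-1] >= high:
        return "late"
    return "other"


def _linear_gof(x: np.ndarray, y: np.ndarray) -> float:
    """Closed-form gof of the best linear fit (the squared Pearson r).

    The linear prototype's sse_ratio optimum has the exact least-squares
    solution, so the permutation loop need not run the simplex for it.
    """
    sxx = np.sum((x - x.mean()) ** 2)
    sst = np.sum((y - y.mean()) ** 2)
    if sxx <= 0 or sst <= 0:
        raise DegenerateTargetError("zero variance in permutation refit")
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    return float(sxy * sxy / (sxx * sst))


def _best_gof(pair: CleanPair, cfg: FitConfig, tag: str) -> float:
    fits = {}
    for proto in list_prototypes():
        key = make_search_key(pair.x_parameter, pair.y_parameter,
                              pair.time_point, pair.population,
                              f"{proto.name}#{tag}")
        try:
            fits[proto.name] = fit(proto, pair, cfg, search_key=key)
        except UnfittableError:
            continue
    choice = select_best(fits)
    if choice is None:
        raise DegenerateTargetError("no prototype fittable")
    return choice[1].gof


def permutation_significance(pair: CleanPair, policy: str = "refit-linear",
                             n_permutations: int = 199, seed: int = 0,
                             cfg: FitConfig | None = None) -> float:
    """Exploratory permutation p-value for one pair's association.

    The response is permuted against the predictor B times and refitted
    under the chosen policy — ``refit-linear`` (closed-form linear
    optimum; cheap) or ``refit-best`` (full multistart refit over all
    six prototypes) — and

        p = (1 + #{permuted gof >= observed gof}) / (B + 1).

    Deterministic given ``seed``.  This construction is the package's
    own; no multiplicity correction is applied.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if policy not in ("refit-linear", "refit-best"):
        raise ValueError(f"unknown policy {policy!r}")
    x = np.asarray(pair.x_values, dtype=float)
    y = np.asarray(pair.y_values, dtype=float)
    if np.sum((y - y.mean()) ** 2) <= 0 or np.sum((x - x.mean()) ** 2) <= 0:
        raise DegenerateTargetError(
            "constant vector: permutation test undefined")

    cfg = cfg or FitConfig()
    if policy == "refit-linear":
        observed = _linear_gof(x, y)
    else:
        observed = _best_gof(pair, cfg, "obs")

    rng = np.random.default_rng(seed)
    exceed = 0
    for b in range(n_permutations):
        yp = rng.permutation(y)
        if policy == "refit-linear":
            g = _linear_gof(x, yp)
        else:
            perm_pair = CleanPair(x, yp, pair.subject_ids,
                                  pair.x_parameter, pair.y_parameter,
                                  pair.time_point, pair.population)
            g = _best_gof(perm_pair, cfg, f"perm{b}")
        if g >= observed:
            exceed += 1
    return (1 + exceed) / (n_permutations + 1)


def seriate_matrix(m: GofMatrix | pd.DataFrame | np.ndarray) -> np.ndarray:
    """Greedy nearest-neighbour row/column ordering for cluster hints.

    Rows are compared by Euclidean distance between their gof profiles
    (undefined entries counted as 0 for the distance only); starting
    from the first catalogue row, the nearest unvisited row follows,
    ties resolved to the lowest index.  Returns an index permutation;
    stored values are never altered.
    """
    if isinstance(m, GofMatrix):
        vals = m.gof_values
    elif isinstance(m, pd.DataFrame):
        vals = m.to_numpy(dtype=float)
    else:
        vals = np.asarray(m, dtype=float)
    if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
        raise ValueError("seriation needs a square matrix")
    p = vals.shape[0]
    prof = np.where(np.isfinite(vals), vals, 0.0)
    dist = np.sqrt(((prof[:, None, :] - prof[None, :, :]) ** 2).sum(axis=2))
    order = [0]
    visited = np.zeros(p, dtype=bool)
    visited[0] = True
    while len(order) < p:
        d = dist[order[-1]].copy()
        d[visited] = np.inf
        nxt = int(np.argmin(d))  # argmin takes the lowest index on ties
        order.append(nxt)
        visited[nxt] = True
    return np.asarray(order)
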