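"""Normalized-SSE curve fitting by Monte-Carlo multistart downhill simplex.

The objective for every regression task is the *normalized* sum of
squared errors

    sse_ratio(params) = sum_i (f(x_i) - y_i)**2 / sum_i (ybar - y_i)**2,

i.e. the residual sum of squares over the total sum of squares about
the mean of the response.  Goodness of fit is ``1 - sse_ratio`` — the
R²-analogue that is also meaningful for the non-linear families, where
a Pearson coefficient is not.  A fit no better than the constant-mean
model scores gof 0; worse fits go negative; gof 1 means zero residuals.

Because the non-linear prototypes admit multiple local minima, each
task runs ``n_starts`` independent Nelder–Mead (downhill simplex)
minimizations from start points drawn uniformly at random inside a
data-driven *start box*, and keeps the best terminal point.  The
simplex method is used deliberately: it needs no derivatives, no
convexity, and tolerates the +inf penalty used for parameter vectors
outside a family's domain.

All restarts advance in lockstep through a single vectorized simplex
loop (one numpy batch per iteration), which is what makes screening
hundreds of thousands of tasks tractable.  Randomness is fully
deterministic: the per-task seed is derived from the global seed and
the task's search key, so any single fit is reproducible in isolation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .errors import (DegenerateInputError, DegenerateTargetError,
                     UnfittableError)
from .prototypes import PrototypeSpec, evaluate_batch

__all__ = [
    "FitConfig", "FitResult", "normalized_sse", "goodness_of_fit",
    "start_box", "fit", "fit_batch",
]



@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for one screening run.

    ``max_iterations`` is per simplex run; ``None`` means 500·arity,
    supplemented by up to three restart runs from the incumbent best
    point (restarting a collapsed simplex recovers terminal accuracy
    far more cheaply than one very long run).  ``bound_inflation``
    widens the data-driven start boxes (see :func:`start_box`).
    """

    n_starts: int = 20
    max_iterations: int | None = None
    x_tolerance: float = 1e-8
    f_tolerance: float = 1e-10
    rng_seed: int = 1
    bound_inflation: float = 2.0
    polish_rounds: int = 3

    def __post_init__(self):
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.x_tolerance <= 0 or self.f_tolerance <= 0:
            raise ValueError("tolerances must be > 0")
        if self.bound_inflation <= 0:
            raise ValueError("bound_inflation must be > 0")
        if self.polish_rounds < 0:
            raise ValueError("polish_rounds must be >= 0")

    def iterations_for(self, arity: int) -> int:
        return (500 * arity if self.max_iterations is None
                else self.max_iterations)


@dataclass(frozen=True)
class FitResult:
    """Outcome of one regression task."""

    prototype: str
    params: tuple[float, ...]
    sse_ratio: float
    gof: float
    n: int
    converged: bool
    n_starts_used: int
    search_key: str = ""

    def __post_init__(self):
        if np.isfinite(self.sse_ratio):
            assert abs(self.gof - (1.0 - self.sse_ratio)) < 1e-12


def normalized_sse(proto: PrototypeSpec, params, pair) -> float:
    """The screening objective: SSE over SST; +inf if infeasible.

    Raises :class:`DegenerateTargetError` if the response is constant
    (SST == 0); such pairs carry no signal and must be skipped.
    """
    y = np.asarray(pair.y_values, dtype=float)
    x = np.asarray(pair.x_values, dtype=float)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0.0:
        raise DegenerateTargetError(
            f"constant response for pair ({pair.x_parameter}, "
            f"{pair.y_parameter}); SST = 0")
    params = np.asarray(params, dtype=float)
    if params.shape != (proto.arity,):
        raise ValueError(f"{proto.name} expects {proto.arity} parameters")
    f = evaluate_batch(proto, params[np.newaxis, :], x)[0]
    if not np.all(np.isfinite(f)):
        return float("inf")
    return float(np.sum((f - y) ** 2) / sst)


def goodness_of_fit(sse_ratio: float) -> float:
    """gof = 1 - sse_ratio; may be negative for fits worse than the mean."""
    if sse_ratio < 0:
        raise ValueError("sse_ratio must be nonnegative")
    return 1.0 - sse_ratio


def _inflate(lo: float, hi: float, factor: float) -> tuple[float, float]:
    mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo) * factor
    return (mid - half, mid + half)


def start_box(proto: PrototypeSpec, pair,
              inflation: float = 2.0) -> list[tuple[float, float]]:
    """Data-driven per-parameter start intervals for the Monte-Carlo draws.

    Construction (inflation factor λ, x-range xr, y-range yr):

    * offset/asymptote-like parameters span the observed y-range
      inflated by λ;
    * slope-like parameters of degree k span ±λ·yr/xr**k;
    * the sigmoid location ``e`` spans the inflated x-range; its rate
      ``d`` and the exponential rate ``b`` span ±λ/xr;
    * the logarithmic ``b`` spans ±λ/xr with ``c`` bounded below so
      that b·x + c > 0 at every start point.

    The boxes scale with the data (doubling y doubles every
    intercept/asymptote interval), so plausible optima lie inside for
    any measurement units.
    """
    x = np.asarray(pair.x_values, dtype=float)
    y = np.asarray(pair.y_values, dtype=float)
    xr = float(x.max() - x.min())
    yr = float(y.max() - y.min())
    if xr <= 0:
        raise DegenerateInputError("zero x-range: no start box")
    if yr <= 0:
        raise DegenerateInputError("zero y-range: no start box")
    ybox = _inflate(float(y.min()), float(y.max()), inflation)
    xbox = _inflate(float(x.min()), float(x.max()), inflation)

    def slope(k: int) -> tuple[float, float]:
        s = inflation * yr / xr**k
        return (-s, s)

    rate = inflation / xr
    name = proto.name
    if name == "linear":
        return [slope(1), ybox]
    if name == "quadratic":
        return [slope(2), slope(1), ybox]
    if name == "cubic":
        return [slope(3), slope(2), slope(1), ybox]
    if name == "exponential":
        return [ybox, (-rate, rate), (-inflation, inflation), ybox]
    if name == "sigmoid":
        return [ybox, ybox, ybox, (-rate, rate), xbox]
    if name == "logarithmic":
        # any |b| <= rate keeps b*x + c >= c_lo - rate*max|x| > 0
        c_lo = rate * float(np.max(np.abs(x))) + 1e-6 * (1.0 + rate)
        return [ybox, (-rate, rate),
                (c_lo, c_lo + inflation * max(1.0, c_lo)), ybox]
    raise KeyError(f"unknown prototype {name!r}")


# ---------------------------------------------------------------------------
# Vectorized lockstep Nelder-Mead
# ---------------------------------------------------------------------------

def _nelder_mead_batch(objective, x0: np.ndarray, maxiter: int,
                       xatol: float, fatol: float):
    """Minimize ``objective`` from every row of ``x0`` simultaneously.

    ``objective(P, idx)`` maps an (r, k) parameter stack belonging to
    simplices ``idx`` to (r,) values (non-finite treated as +inf); the
    index argument lets one closure serve many cells with different
    data.  Uses the adaptive reflection/expansion/contraction/shrink
    coefficients of Gao & Han, the same family scipy's ``Nelder-Mead``
    uses for higher dimensions; each of the m simplices evolves
    independently but the loop advances them together one batched
    evaluation per step.

    Returns (xbest (m,k), fbest (m,), converged (m,) bool).
    """
    m, k = x0.shape
    rho, chi = 1.0, 1.0 + 2.0 / k
    psi, sigma = 0.75 - 1.0 / (2.0 * k), 1.0 - 1.0 / k

    def call(pts: np.ndarray, idx: np.ndarray) -> np.ndarray:
        f = np.asarray(objective(pts, idx), dtype=float)
        return np.where(np.isfinite(f), f, np.inf)

    all_idx = np.arange(m)
    # scipy-style initial simplex: perturb each coordinate by 5 %
    # (absolute 2.5e-4 where the coordinate is zero)
    simplex = np.repeat(x0[:, np.newaxis, :], k + 1, axis=1)
    for j in range(k):
        col = simplex[:, j + 1, j]
        simplex[:, j + 1, j] = np.where(col != 0.0, col * 1.05, 2.5e-4)
    fvals = np.stack([call(simplex[:, v, :], all_idx) for v in range(k + 1)],
                     axis=1)

    active = np.ones(m, dtype=bool)
    converged = np.zeros(m, dtype=bool)

    for _ in range(maxiter):
        if not active.any():
            break
        order = np.argsort(fvals, axis=1, kind="stable")
        take = np.arange(m)[:, None]
        fvals = fvals[take, order]
        simplex = simplex[take[:, :, None], order[:, :, None],
                          np.arange(k)[None, None, :]]

        best_x = simplex[:, 0, :]
        with np.errstate(invalid="ignore"):
            fspread = fvals[:, -1] - fvals[:, 0]
            xspread = np.max(np.abs(simplex - best_x[:, None, :]),
                             axis=(1, 2))
        all_inf = ~np.isfinite(fvals[:, 0])
        tol_met = (np.isfinite(fspread) & (fspread <= fatol)
                   & (xspread <= xatol))
        done_now = active & (all_inf | tol_met)
        converged |= done_now & ~all_inf
        active &= ~done_now
        if not active.any():
            break

        idx = np.flatnonzero(active)
        cent = simplex[idx, :k, :].mean(axis=1)
        worst = simplex[idx, k, :]
        xr = cent + rho * (cent - worst)
        fr = call(xr, idx)

        f0 = fvals[idx, 0]
        fk1 = fvals[idx, k - 1]
        fk = fvals[idx, k]

        new_x = worst.copy()
        new_f = fk.copy()
        shrink = np.zeros(idx.size, dtype=bool)

        # expansion branch
        m1 = fr < f0
        if m1.any():
            xe = cent[m1] + rho * chi * (cent[m1] - worst[m1])
            fe = call(xe, idx[m1])
            better = fe < fr[m1]
            sub = np.flatnonzero(m1)
            new_x[sub[better]] = xe[better]
            new_f[sub[better]] = fe[better]
            new_x[sub[~better]] = xr[m1][~better]
            new_f[sub[~better]] = fr[m1][~better]

        # plain reflection
        m2 = (~m1) & (fr < fk1)
        new_x[m2] = xr[m2]
        new_f[m2] = fr[m2]

        # outside contraction
        m3 = (~m1) & (~m2) & (fr < fk)
        if m3.any():
            xc = cent[m3] + psi * rho * (cent[m3] - worst[m3])
            fc = call(xc, idx[m3])
            ok = fc <= fr[m3]
            sub = np.flatnonzero(m3)
            new_x[sub[ok]] = xc[ok]
            new_f[sub[ok]] = fc[ok]
            shrink[sub[~ok]] = True

        # inside contraction
        m4 = (~m1) & (~m2) & (~m3)
        if m4.any():
            xcc = cent[m4] - psi * (cent[m4] - worst[m4])
            fcc = call(xcc, idx[m4])
            ok = fcc < fk[m4]
            sub = np.flatnonzero(m4)
            new_x[sub[ok]] = xcc[ok]
            new_f[sub[ok]] = fcc[ok]
            shrink[sub[~ok]] = True

        keep = ~shrink
        simplex[idx[keep], k, :] = new_x[keep]
        fvals[idx[keep], k] = new_f[keep]

        if shrink.any():
            sidx = idx[shrink]
            v0 = simplex[sidx, 0:1, :]
            simplex[sidx] = v0 + sigma * (simplex[sidx] - v0)
            for v in range(1, k + 1):
                fvals[sidx, v] = call(simplex[sidx, v, :], sidx)

    order = np.argsort(fvals, axis=1, kind="stable")
    best = order[:, 0]
    rows = np.arange(m)
    return simplex[rows, best, :], fvals[rows, best], converged


def derive_task_seed(global_seed: int, search_key: str) -> np.random.SeedSequence:
    """Deterministic per-task seed from the global seed and search key."""
    digest = hashlib.sha256(search_key.encode()).digest()
    h = int.from_bytes(digest[:8], "big")
    return np.random.SeedSequence(entropy=(int(global_seed) & (2**63 - 1), h))


def fit(proto: PrototypeSpec, pair, cfg: FitConfig | None = None,
        search_key: str = "") -> FitResult:
    """Multistart downhill-simplex fit of one prototype to one clean pair.

    Runs ``cfg.n_starts`` lockstep simplex minimizations from uniform
    draws inside :func:`start_box`, keeps the lowest terminal
    sse_ratio, then restarts up to three times from that point while it
    keeps improving by more than ``f_tolerance``.  Deterministic given
    (pair, cfg, search_key).

    Raises :class:`UnfittableError` (a skip signal, not a failure) when
    n < arity + 1, the response is constant, or the predictor has zero
    range.
    """
    cfg = cfg or FitConfig()
    x = np.asarray(pair.x_values, dtype=float)
    y = np.asarray(pair.y_values, dtype=float)
    n = x.size
    if n < proto.arity + 1:
        raise UnfittableError(
            "n_too_small", f"n={n} < arity+1={proto.arity + 1}")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0.0:
        raise UnfittableError("sst_zero", "constant response (SST = 0)")
    try:
        box = start_box(proto, pair, cfg.bound_inflation)
    except DegenerateInputError as exc:
        raise UnfittableError("degenerate_x", str(exc)) from exc

    def objective(P: np.ndarray, idx: np.ndarray) -> np.ndarray:
        f = evaluate_batch(proto, P, x)
        with np.errstate(invalid="ignore"):
            sse = np.sum((f - y[np.newaxis, :]) ** 2, axis=1)
        return sse / sst

    key = search_key or (f"{pair.x_parameter}~{pair.y_parameter}"
                         f"@t{pair.time_point}|{pair.population}|{proto.name}")
    rng = np.random.default_rng(derive_task_seed(cfg.rng_seed, key))
    lo = np.array([b[0] for b in box])
    hi = np.array([b[1] for b in box])
    starts = rng.uniform(lo, hi, size=(cfg.n_starts, proto.arity))

    maxiter = cfg.iterations_for(proto.arity)
    xb, fb, conv = _nelder_mead_batch(objective, starts, maxiter,
                                      cfg.x_tolerance, cfg.f_tolerance)
    i = int(np.argmin(fb))
    best_x, best_f = xb[i], float(fb[i])
    any_converged = bool(conv.any()) and np.isfinite(best_f)

    if np.isfinite(best_f):
        for _ in range(cfg.polish_rounds):
            px, pf, pconv = _nelder_mead_batch(
                objective, best_x[np.newaxis, :], maxiter,
                cfg.x_tolerance, cfg.f_tolerance)
            improved = float(pf[0]) < best_f - cfg.f_tolerance
            if float(pf[0]) < best_f:
                best_x, best_f = px[0], float(pf[0])
                any_converged = any_converged or bool(pconv[0])
            if not improved:
                break

    gof = 1.0 - best_f if np.isfinite(best_f) else float("-inf")
    return FitResult(
        prototype=proto.name,
        params=tuple(float(v) for v in best_x),
        sse_ratio=best_f,
        gof=gof,
        n=int(n),
        converged=any_converged,
        n_starts_used=cfg.n_starts,
        search_key=key,
    )


def fit_batch(proto: PrototypeSpec, pairs, cfg: FitConfig | None = None,
              search_keys=None):
    """Fit one prototype to many clean pairs in a single lockstep sweep.

    All restarts of all pairs advance through one vectorized simplex
    loop, which amortizes the per-iteration Python overhead over the
    whole slice — the difference between hours and minutes on a full
    parameter-matrix screen.  Per-pair results are identical to what
    :func:`fit` computes (same start draws, same arithmetic, same
    tolerances); a test asserts the equivalence.

    Returns a list aligned with ``pairs`` whose elements are either a
    :class:`FitResult` or an :class:`UnfittableError` carrying the skip
    reason for that pair.
    """
    cfg = cfg or FitConfig()
    k = proto.arity
    out: list = [None] * len(pairs)
    keep, xs, ys, keys = [], [], [], []
    for i, pair in enumerate(pairs):
        key = (search_keys[i] if search_keys is not None else
               f"{pair.x_parameter}~{pair.y_parameter}@t{pair.time_point}"
               f"|{pair.population}|{proto.name}")
        x = np.asarray(pair.x_values, dtype=float)
        y = np.asarray(pair.y_values, dtype=float)
        if x.size < k + 1:
            out[i] = UnfittableError("n_too_small",
                                     f"n={x.size} < arity+1={k + 1}")
            continue
        if float(np.sum((y - y.mean()) ** 2)) <= 0.0:
            out[i] = UnfittableError("sst_zero", "constant response")
            continue
        if float(x.max() - x.min()) <= 0.0 or float(y.max() - y.min()) <= 0.0:
            out[i] = UnfittableError("degenerate_x", "zero predictor range")
            continue
        keep.append(i)
        xs.append(x)
        ys.append(y)
        keys.append(key)
    if not keep:
        return out

    ncells = len(keep)
    nmax = max(x.size for x in xs)
    # pad each cell's abscissa with its median so padded points stay in
    # the prototype's natural domain; the mask removes them from SSE
    X = np.empty((ncells, nmax))
    Y = np.zeros((ncells, nmax))
    M = np.zeros((ncells, nmax), dtype=bool)
    sst = np.empty(ncells)
    for c, (x, y) in enumerate(zip(xs, ys)):
        X[c, :x.size] = x
        X[c, x.size:] = np.median(x)
        Y[c, :y.size] = y
        M[c, :y.size] = True
        sst[c] = np.sum((y - y.mean()) ** 2)

    starts = np.empty((ncells * cfg.n_starts, k))
    boxes = []
    for c, i in enumerate(keep):
        box = start_box(proto, pairs[i], cfg.bound_inflation)
        boxes.append(box)
        lo = np.array([b[0] for b in box])
        hi = np.array([b[1] for b in box])
        rng = np.random.default_rng(derive_task_seed(cfg.rng_seed, keys[c]))
        starts[c * cfg.n_starts:(c + 1) * cfg.n_starts] = rng.uniform(
            lo, hi, size=(cfg.n_starts, k))
    cell_of = np.repeat(np.arange(ncells), cfg.n_starts)

    def objective(P: np.ndarray, idx: np.ndarray) -> np.ndarray:
        cells = cell_of[idx]
        f = evaluate_batch(proto, P, X[cells])
        with np.errstate(invalid="ignore"):
            resid = np.where(M[cells], f - Y[cells], 0.0)
            sse = np.einsum("ij,ij->i", resid, resid)
            bad = np.any(M[cells] & ~np.isfinite(f), axis=1)
        val = sse / sst[cells]
        val[bad] = np.inf
        return val

    maxiter = cfg.iterations_for(k)
    xb, fb, conv = _nelder_mead_batch(objective, starts, maxiter,
                                      cfg.x_tolerance, cfg.f_tolerance)

    fb_cells = fb.reshape(ncells, cfg.n_starts)
    best_start = np.argmin(fb_cells, axis=1)
    rows = best_start + np.arange(ncells) * cfg.n_starts
    best_x = xb[rows].copy()
    best_f = fb[rows].copy()
    any_conv = conv.reshape(ncells, cfg.n_starts).any(axis=1)

    def polish_objective(P: np.ndarray, idx: np.ndarray) -> np.ndarray:
        f = evaluate_batch(proto, P, X[idx])
        with np.errstate(invalid="ignore"):
            resid = np.where(M[idx], f - Y[idx], 0.0)
            sse = np.einsum("ij,ij->i", resid, resid)
            bad = np.any(M[idx] & ~np.isfinite(f), axis=1)
        val = sse / sst[idx]
        val[bad] = np.inf
        return val

    todo = np.isfinite(best_f)
    for _ in range(cfg.polish_rounds):
        if not todo.any():
            break
        idx = np.flatnonzero(todo)
        px, pf, pconv = _nelder_mead_batch(
            lambda P, j, idx=idx: polish_objective(P, idx[j]),
            best_x[idx], maxiter, cfg.x_tolerance, cfg.f_tolerance)
        improved = pf < best_f[idx] - cfg.f_tolerance
        better = pf < best_f[idx]
        best_x[idx[better]] = px[better]
        best_f[idx[better]] = pf[better]
        any_conv[idx[better]] |= pconv[better]
        nxt = np.zeros_like(todo)
        nxt[idx[improved]] = True
        todo = nxt

    for c, i in enumerate(keep):
        f = float(best_f[c])
        out[i] = FitResult(
            prototype=proto.name,
            params=tuple(float(v) for v in best_x[c]),
            sse_ratio=f,
            gof=1.0 - f if np.isfinite(f) else float("-inf"),
            n=int(xs[c].size),
            converged=bool(any_conv[c]) and np.isfinite(f),
            n_starts_used=cfg.n_starts,
            search_key=keys[c],
        )
    return out
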