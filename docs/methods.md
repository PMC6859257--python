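# Methods

## Scope and model

`pairscreen` is a secondary-analysis engine for pooled longitudinal
cohort data.  Its unit of work is the *regression task*: one ordered
parameter pair (x, y), one time point, one subject population, one
functional prototype.  The engine fits every task of a cartesian grid
and mines the resulting goodness-of-fit matrices for candidate
prognostic markers.  It deliberately stops short of causal claims,
multiple regression over more than two parameters, and formal cluster
analysis — matrices, rankings and labels are decision support for
manual reading.

### Data model

Input is a long-format table, one row per (subject, time point,
parameter) measurement, plus four per-subject classifiers: treatment
(binary), survival (binary), subject id, study id.  Invariants enforced
at load time: at most one measurement per (subject, time, parameter)
triple; every row's time point belongs to the declared grid (default
0, 60, 120, 180, 240, 300 minutes); classifier values are normalized
case-insensitively through a configurable vocabulary map, and subjects
with missing or inconsistent classifiers are rejected rather than
guessed.  Empty cells and the tokens `NA`, `NaN`, `N/A`, `null`, `.`
(case-insensitive) are missing values; unparseable numeric cells become
missing with a logged count.

Crossing the treatment and survival filters, minus the two strata that
would pool both treatment arms within one survival outcome, gives the
seven canonical populations I–VII.  Clean vectors are pairwise-complete
with no imputation, ordered by lexicographic subject id so that every
fit is reproducible.

### Objective and goodness of fit

All prototypes minimize the normalized sum of squared errors
`sse_ratio = SSE / SST` (SST about the mean of y).  Goodness of fit is
defined once, everywhere, as `GoF = 1 − sse_ratio`: 1 means zero
residuals, 0 means no better than the constant-mean model, negative
values are worse than the mean.  Filtering and ranking use this scale
(default candidate threshold GoF ≥ 0.7); only on it does a "minimum
goodness of fit" make sense.  Pairs with SST = 0 (constant response)
are skipped as degenerate, not fitted.

### Prototypes

Six families (linear 2, sigmoid 5, exponential 4, quadratic 3, cubic 4,
logarithmic 4 free parameters) in the fixed canonical order linear,
sigmoid, exponential, quadratic, cubic, logarithmic.  Two forms carry
redundant parameter directions (logarithmic `a` and `d` enter only as
a + d; exponential `a` and `c` only as a·e^c).  They are kept verbatim:
the simplex optimizer needs no identifiability and GoF is unaffected,
but individual coordinates along redundant directions are not
reportable quantities.  The exponential is implemented with the offset
outside the exponent, `a·exp(b·x + c) + d`, matching the
four-parameter shape of its siblings.  Domain violations (logarithm of
a non-positive argument, |exponent| > 700, vanishing sigmoid
denominator) return an infeasible flag rather than raising; the
optimizer scores infeasible parameter vectors +∞ and moves on.

## Optimizer

Each task runs `n_starts` independent Nelder–Mead (downhill simplex)
minimizations from points drawn uniformly in a data-driven start box,
and keeps the lowest terminal objective.  The simplex method is chosen
because it needs no derivatives, continuity or convexity and tolerates
the +∞ infeasibility penalty; a simplex whose vertices are all +∞
terminates unconverged and that start is discarded.

**Start boxes** (inflation factor λ = 2 by default; x-range xr, y-range
yr): offset/asymptote-like parameters span the observed y-range
inflated by λ; degree-k slope-like parameters span ±λ·yr/xrᵏ; the
sigmoid location `e` spans the inflated x-range; rate parameters
(sigmoid `d`, exponential and logarithmic `b`) span ±λ/xr; the
logarithmic `c` is bounded below so b·x + c > 0 at every admissible
start.  The boxes scale equivariantly with the data, so the same
defaults work in any measurement units.  A zero x- or y-range is a
degenerate input and the task is skipped.

**Implementation.**  The simplex loop is vectorized: all restarts of
all cells in a (time, population, prototype) slice advance in lockstep,
one batched objective evaluation per iteration, using the adaptive
reflection/expansion/contraction/shrink coefficients of Gao & Han
(the same family scipy uses for higher dimensions) and scipy-style
initial simplices (5 % coordinate perturbation).  Cells of different
sample size are padded to a common length with their median x value and
masked out of the SSE.  This batching is purely an execution strategy —
per-task results match independent single fits to numerical precision,
and a test asserts it — but it is the difference between hours and
minutes on a full screen.

**Defaults** (all exposed in `FitConfig`): `n_starts` 20;
`max_iterations` 500·arity per simplex run, supplemented by up to 3
restart ("polish") runs from the incumbent best point — restarting a
collapsed simplex recovers terminal accuracy far more cheaply than one
very long run, and the polish step only ever improves the objective;
`x_tolerance` 1e−8 and `f_tolerance` 1e−10 (simplex spread termination);
`bound_inflation` 2.  Randomness: the per-task seed is derived from the
global seed and the task's search key via SHA-256, so any single fit is
reproducible in isolation and screens are deterministic byte-for-byte.
Restart draws are nested: the first k of k+m starts are identical, so
adding starts can only improve the best objective (exact with
`polish_rounds=0`, which is how the property is tested).

**Fit preconditions.**  n ≥ arity + 1 per task (an exact interpolation
through as many points as parameters is not a discovery), SST > 0,
nonzero x-range.  Violations are skip signals with machine-readable
reasons, counted so that fitted + skipped always equals the grid's task
count.

## Model selection

Per cell, the best family is the one with maximal GoF, with one
refinement: families whose GoF lies within `tie_tolerance` (default
1e−3) of the maximum count as tied, and ties resolve to the fewest free
parameters, then canonical order.  Without the tolerance the nested
families (cubic ⊇ quadratic ⊇ linear) would beat the true family by a
noise-level margin on essentially every noisy cell; one part in a
thousand of explained variance is treated as not worth two extra
parameters.  Consequently the "best" matrix dominates each
single-prototype matrix up to that same tolerance, not exactly.  For
the linear slice the signed Pearson coefficient (sign of the fitted
slope times √GoF) is stored alongside; for non-linear families no
correlation coefficient is standard, so GoF alone is reported.

Self-pairs and both orientations are enumerated and fitted — the grid
counts (2025 per slice, 510 300 for a 45-parameter study) include them —
but candidate lists flag self-pairs as trivial and by default keep only
the better-fitting orientation of each unordered pair.

## Discovery strategies

* **Filtering**: keep cells with n ≥ 12 and GoF ≥ 0.7 (both
  configurable).
* **Population differences**: entry-wise GoF difference between two
  population slices of the same time point; cells ranked by absolute
  difference (the signed matrix is also emitted, since a coupling
  present only in non-survivors is a negative difference for
  survivors-minus-non-survivors).
* **Time trends**: per-cell GoF profile across the grid; change score
  max − min over defined entries (at least 2 required) — robust to
  single undefined entries and invariant to permuting the time axis.
  Profiles are labeled `lockstep` (all entries ≥ high), `early` (first
  ≥ high, last ≤ low), `late` (first ≤ low, last ≥ high) or `other`,
  with thresholds high = 0.7, low = 0.3 by default.
* **Seriation**: greedy nearest-neighbour ordering on Euclidean row
  distance (undefined entries imputed 0 for the distance only),
  starting from the first catalogue row, ties to the lowest index.  A
  hint for visual cluster reading, not a cluster analysis.
* **Permutation significance** (the package's own construction; the
  notion of a per-cell significance is otherwise left open): permute y
  against x B times (default 199), refit under the chosen policy, and
  report p = (1 + #{permuted GoF ≥ observed}) / (B + 1).  Policies:
  `refit-best` (full multistart refit over all six families — the
  honest but expensive null) and `refit-linear` (the linear family's
  optimum, computed in closed form since the linear sse_ratio minimum
  is exactly the least-squares solution).  These p-values are
  exploratory; no correction for the ~10⁵ cells of a full screen is
  attempted.

## Synthetic cohorts

The generator emulates the *structure* of the pooled study design:
63 treated + 57 control subjects, 45 parameters, six time points, 11
studies by default; binary survival drawn per subject (defaults 0.55
treated, 0.97 control — roughly half of treated animals die in such
models, control deaths are rare, so the control non-survivor population
V is realistically tiny and downstream code must tolerate n below any
filter there).  Unplanted parameters are independent Gaussians with
per-parameter location and scale; planted relations set
y = f(x) + ε, ε ~ N(0, noise_sd · curve range), only for subjects in
the active populations and times; missingness is completely at random.
Planted x values are uniform on a declared window (default 0–10) wide
enough to express each family's signature curvature — the bundled
default parameter vectors put the sigmoid's inflection inside the
window, give the exponential and logarithm strong curvature and the
cubic two interior turning points, so the families are mutually
distinguishable at percent-level noise.

What the generator does **not** emulate: physiological distributions or
units of real parameters, correlated missingness (dropout after death),
measurement error on x, study- or experimenter-level batch effects.
Passing tests therefore demonstrate the engine's statistical machinery
— recovery, selection, null behavior — not field performance on any
real cohort.

## Problem sizes in tests and the acceptance script

Simulation-based checks run on scaled-down grids chosen as the smallest
that still exercise the property: ~30-subject cohorts, 2–5 parameters,
one to four time points; 20 seeded cohorts per family for
identification at 1 % noise; 10 seeds for null pass rates and
difference rankings; 200 repetitions at B = 99 for the permutation
type-I error.  The full 45-parameter enumeration is checked by
counting, not by fitting all 510 300 tasks.

## Known limitations

* The sigmoid is implemented exactly in its printed five-parameter
  nesting; it is an unusual parameterization whose asymptotes are `a`
  and `a + (b−a)·b`, and some of its parameter combinations are only
  weakly identified.  Fitted curves are reliable; individual sigmoid
  coordinates should be interpreted with care.
* Multistart optimization is a heuristic: a global optimum is not
  guaranteed, only made likely by the start-box coverage, restart
  count and polish step (oracle tests bound the polynomial families to
  1e−6 of the closed-form optimum).
* The permutation test assumes exchangeability of y across subjects
  within the slice; it ignores study structure.
* Candidate lists are exploratory screens, not confirmatory inference.
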