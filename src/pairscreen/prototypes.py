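"""The six functional prototypes fitted to every parameter pair.

Each prototype is a small parametric curve family ``y = f(params, x)``.
The screen postulates six of them — one linear, five non-linear — and
fits all six to every pair of clinical parameters, keeping whichever
explains the response best.  Families and parameter letters:

========== ====== =====================================================
name       arity  f(x)
========== ====== =====================================================
linear       2    a*x + b
sigmoid      5    a + (b-a) * (b*c / (c + (b-c)*exp(-d*b*(x-e))))
exponential  4    a*exp(b*x + c) + d
quadratic    3    a*x**2 + b*x + c
cubic        4    a*x**3 + b*x**2 + c*x + d
logarithmic  4    a + ln(b*x + c) + d
========== ====== =====================================================

Some families carry redundant directions on purpose (the logarithmic
``a`` and ``d`` enter only as ``a + d``; the exponential ``a`` and ``c``
only as ``a*e**c``).  The simplex optimizer does not need identifiable
parameters, goodness of fit is unaffected, and the printed forms are
kept verbatim; individual coordinates along redundant directions are
not reportable quantities.

Evaluation outside a family's domain (logarithm of a non-positive
argument, overflowing exponent, vanishing sigmoid denominator) yields
``None`` — an *infeasible* flag the optimizer scores as +inf — rather
than an exception, so a simplex can step out of the domain and recover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PrototypeSpec", "list_prototypes", "get_prototype", "evaluate"]

# exp() overflows float64 just above 709; clamp-check, do not clamp-value
_EXP_MAX = 700.0


@dataclass(frozen=True)
class PrototypeSpec:
    """One curve family: a name plus its ordered free parameters."""

    name: str
    parameter_names: tuple[str, ...]

    @property
    def arity(self) -> int:
        return len(self.parameter_names)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PrototypeSpec({self.name!r}, arity={self.arity})"


LINEAR = PrototypeSpec("linear", ("a", "b"))
SIGMOID = PrototypeSpec("sigmoid", ("a", "b", "c", "d", "e"))
EXPONENTIAL = PrototypeSpec("exponential", ("a", "b", "c", "d"))
QUADRATIC = PrototypeSpec("quadratic", ("a", "b", "c"))
CUBIC = PrototypeSpec("cubic", ("a", "b", "c", "d"))
LOGARITHMIC = PrototypeSpec("logarithmic", ("a", "b", "c", "d"))

#: Canonical order — fixed; used for tie-breaking and search keys.
_CANONICAL = (LINEAR, SIGMOID, EXPONENTIAL, QUADRATIC, CUBIC, LOGARITHMIC)
_BY_NAME = {p.name: p for p in _CANONICAL}


def list_prototypes() -> list[PrototypeSpec]:
    """Return the six prototypes in canonical order.

    The order (linear, sigmoid, exponential, quadratic, cubic,
    logarithmic) is part of the package contract: it breaks ties in
    model selection and fixes the enumeration order of the task grid.
    """
    return list(_CANONICAL)


def get_prototype(name: str) -> PrototypeSpec:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown prototype {name!r}; "
                       f"known: {sorted(_BY_NAME)}") from None


def _predict(name: str, p: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Raw batched prediction; ``p`` has shape (m, arity), returns (m, n).

    ``x`` may be a shared abscissa vector (n,) or one row per parameter
    vector (m, n).  Invalid points come out non-finite (nan/inf);
    callers decide whether that means an infeasible parameter vector.
    """
    x = np.atleast_2d(x)
    with np.errstate(all="ignore"):
        if name == "linear":
            return p[:, 0:1] * x + p[:, 1:2]
        if name == "quadratic":
            return p[:, 0:1] * x**2 + p[:, 1:2] * x + p[:, 2:3]
        if name == "cubic":
            return (p[:, 0:1] * x**3 + p[:, 1:2] * x**2
                    + p[:, 2:3] * x + p[:, 3:4])
        if name == "exponential":
            arg = p[:, 1:2] * x + p[:, 2:3]
            bad = np.abs(arg) > _EXP_MAX
            out = p[:, 0:1] * np.exp(np.where(bad, 0.0, arg)) + p[:, 3:4]
            out[bad.nonzero()[0]] = np.nan
            return out
        if name == "logarithmic":
            arg = p[:, 1:2] * x + p[:, 2:3]
            return p[:, 0:1] + np.log(arg) + p[:, 3:4]
        if name == "sigmoid":
            a, b, c, d, e = (p[:, i:i + 1] for i in range(5))
            expo = -d * b * (x - e)
            bad = np.abs(expo) > _EXP_MAX
            den = c + (b - c) * np.exp(np.where(bad, 0.0, expo))
            out = a + (b - a) * (b * c / den)
            # overflowing exponent with (b-c) of matching sign would be a
            # well-defined limit, but the printed form is kept literal:
            # out-of-range exponents are infeasible.
            out[bad.nonzero()[0]] = np.nan
            return out
    raise KeyError(f"unknown prototype {name!r}")


def evaluate(proto: PrototypeSpec, params, x) -> np.ndarray | None:
    """Evaluate ``proto`` at every point of ``x``; ``None`` if infeasible.

    Infeasible means any evaluation point violates the family's domain
    or overflows float64.  Raises ``ValueError`` on wrong arity.
    """
    params = np.asarray(params, dtype=float)
    if params.shape != (proto.arity,):
        raise ValueError(
            f"{proto.name} expects {proto.arity} parameters "
            f"{proto.parameter_names}, got shape {params.shape}")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    out = _predict(proto.name, params[np.newaxis, :], x)[0]
    if not np.all(np.isfinite(out)):
        return None
    return out


def evaluate_batch(proto: PrototypeSpec, params: np.ndarray,
                   x: np.ndarray) -> np.ndarray:
    """Vectorized evaluation for (m, arity) parameter stacks -> (m, n).

    ``x`` is either one shared abscissa vector or an (m, n) array with
    one row per parameter vector.  Rows with any non-finite prediction
    are returned as-is; the fitting objective maps them to +inf.
    """
    if params.ndim != 2 or params.shape[1] != proto.arity:
        raise ValueError(f"expected (m, {proto.arity}) parameter stack, "
                         f"got {params.shape}")
    return _predict(proto.name, params, np.asarray(x, dtype=float))
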