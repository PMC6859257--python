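"""Exception hierarchy used across the package."""


class PairscreenError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PairscreenError):
    """Input table lacks a required column or has an unusable layout."""


class IntegrityError(PairscreenError):
    """Input data violate a database invariant (e.g. duplicated triples)."""


class UnknownIdentifierError(PairscreenError, KeyError):
    """A parameter id, time point or population name is not declared."""


class DegenerateTargetError(PairscreenError):
    """The response vector has zero total sum of squares (constant y)."""


class DegenerateInputError(PairscreenError):
    """The predictor or response has zero range; no start box exists."""


class UnfittableError(PairscreenError):
    """A regression task cannot be fitted; carries a machine-readable reason.

    Reasons: ``n_too_small``, ``sst_zero``, ``degenerate_x``,
    ``all_infeasible``.
    """

    def __init__(self, reason: str, message: str | None = None):
        self.reason = reason
        super().__init__(message or reason)


class KeyParseError(PairscreenError, ValueError):
    """A search key does not follow the ``px~py@t<t>|pop|proto`` format."""
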