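"""Exception hierarchy for qconj."""


class QconjError(Exception):
    """Base class for all qconj errors."""


class ValidationError(QconjError, ValueError):
    """A membership record failed validation (out-of-range weight, bad field)."""


class SchemaError(QconjError, ValueError):
    """A data file does not conform to the expected schema."""


class RepresentabilityError(QconjError, ValueError):
    """A triplet (or dataset) admits no representation of the requested kind.

    Carries enough context to report *why*: the violated condition or the
    feasibility interval the conjunction weight fell outside of.
    """

    def __init__(self, message: str, *, detail: dict | None = None):
        super().__init__(message)
        self.detail = detail or {}


class DimensionError(QconjError, ValueError):
    """Operands have incompatible dimensions."""
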