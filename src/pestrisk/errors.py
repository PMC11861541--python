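"""Exception hierarchy.

Everything raised on purpose derives from :class:`PestriskError`, so callers
(notably the CLI) can distinguish domain failures from genuine bugs.
"""


class PestriskError(Exception):
    """Base class for all errors raised by this package."""


class TableLoadError(PestriskError):
    """A reference-table file is missing or structurally unreadable."""


class TableValidationError(PestriskError):
    """A reference-table value violates a range or consistency invariant."""


class DomainLookupError(PestriskError, KeyError):
    """An identifier (equipment, formulation, PPE item) has no table entry."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep plain message
        return self.args[0] if self.args else ""


class ProductNotFoundError(DomainLookupError):
    """A product name does not resolve in the product database."""


class ScenarioSchemaError(PestriskError):
    """A scenario config is missing keys or has the wrong structure."""


class ScenarioValidationError(PestriskError):
    """A scenario config parsed but violates a value constraint."""
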