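"""Typed errors shared across the package.

Every malformed input raises one of these; no operation returns a
partially loaded or partially computed object.
"""


class IsotrophError(Exception):
    """Base class for all package errors."""


class SchemaError(IsotrophError):
    """Input table violates the on-disk schema (wrong columns, unknown
    codes, duplicated keys)."""


class ParseError(IsotrophError):
    """A cell could not be parsed (e.g. non-numeric isotope value)."""


class ValidationError(IsotrophError):
    """Parsed values violate a domain invariant (e.g. negative PLFA
    abundance)."""


class DomainError(IsotrophError):
    """Arguments outside the mathematical domain of an operation."""


class ConfigurationError(IsotrophError):
    """Invalid run settings (missing seed, too few draws/chains, ...)."""


class ConvergenceError(IsotrophError):
    """MCMC failed the Gelman-Rubin acceptance rule."""
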