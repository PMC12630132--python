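"""Exception hierarchy.

All user-facing failures derive from :class:`FactorSimError` so callers
(and the CLI) can catch one base class.
"""


class FactorSimError(Exception):
    """Base class for all factorsim errors."""


class ConfigurationError(FactorSimError, ValueError):
    """A simulation configuration is structurally invalid or infeasible."""


class ValidationError(FactorSimError, ValueError):
    """An input value violates a precondition (e.g. negative variance)."""


class IntegrityError(FactorSimError, RuntimeError):
    """Stored artifacts disagree with their manifest (corrupt / truncated)."""
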