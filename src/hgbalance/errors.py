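"""Exception types shared across the package."""


class HgBalanceError(Exception):
    """Base class for all package errors."""


class DomainError(HgBalanceError, ValueError):
    """A physical quantity is outside its valid domain (e.g. negative)."""


class UnitError(HgBalanceError, ValueError):
    """Unknown unit string or conversion between incompatible dimensions."""


class ConfigError(HgBalanceError, ValueError):
    """Configuration file is malformed, incomplete or carries wrong units."""


class SteadyStateError(HgBalanceError, RuntimeError):
    """No steady state exists (e.g. nonzero load with zero loss pathways)."""


class ConvergenceError(HgBalanceError, RuntimeError):
    """The time-stepping oracle failed to converge within its step budget."""
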