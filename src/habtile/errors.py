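"""Exception hierarchy.

All user-facing failures derive from :class:`HabtileError` so the CLI can map
them onto exit codes: validation problems -> 1, infeasible densities -> 2.
"""

from __future__ import annotations


class HabtileError(Exception):
    """Base class for all habtile errors."""


class ValidationError(HabtileError, ValueError):
    """A spec, design or argument violates a documented invariant."""


class UnsupportedComparisonError(HabtileError):
    """Raised when an entropy/level metric is requested for a continuous
    size range: sampling from a continuum carries unbounded information, so
    cross-tile complexity comparison is undefined."""


class InfeasibleDensityError(HabtileError):
    """Placement could not realise the requested object count under the
    containment and buffer constraints.  Carries placement diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class ObjectNotFoundError(HabtileError, KeyError):
    """An edit referenced an object id that is not in the design."""


class ConstraintError(HabtileError):
    """A strict-mode edit would break containment or buffer constraints.

    ``violations`` holds the offending :class:`~habtile.edit.Violation`
    records so callers can report exactly which object pairs clash.
    """

    def __init__(self, message: str, violations=()):
        super().__init__(message)
        self.violations = list(violations)
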