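"""Exception hierarchy for hookquant.

All domain errors derive from :class:`HookQuantError` so callers can catch
one base; most also derive from a matching builtin (``ValueError`` /
``LookupError``) so they behave naturally in generic code.
"""


class HookQuantError(Exception):
    """Base class for all hookquant errors."""


class ValidationError(HookQuantError, ValueError):
    """An input violated a documented invariant; the message names the field."""


class DegenerateProfileError(HookQuantError, ValueError):
    """A staining profile carries no signal (zero total intensity)."""


class DegenerateGeometryError(HookQuantError, ValueError):
    """Landmark geometry does not define the requested construct
    (e.g. the hook-angle bisector for a fully open hook)."""


class NoTissueError(HookQuantError, RuntimeError):
    """No tissue run was found along the bisector ray."""


class OutOfBoundsError(HookQuantError, ValueError):
    """A chord or sampling path leaves the image bounds."""


class MissingCellError(HookQuantError, LookupError):
    """A required genotype / day / concentration cell is absent from a table."""
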