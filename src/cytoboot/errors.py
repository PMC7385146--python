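"""Exception hierarchy.

All package-specific failures derive from :class:`CytobootError` so callers can
catch one base class; subclasses also derive from the closest builtin so that
generic handlers (``except ValueError``) keep working.
"""


class CytobootError(Exception):
    """Base class for all cytoboot errors."""


class ConfigurationError(CytobootError, ValueError):
    """Invalid study/pipeline configuration (bad fractions, unknown names, ...)."""


class FormatError(CytobootError, ValueError):
    """A file does not match the expected on-disk format or marker panel."""


class ConsistencyError(CytobootError, ValueError):
    """Study-level invariants violated (duplicate patient/timepoint, mixed panels)."""


class StateError(CytobootError, RuntimeError):
    """An operation was called on data in the wrong state (e.g. double arcsinh)."""


class ParameterError(CytobootError, ValueError):
    """An argument is outside its valid domain."""


class DesignError(CytobootError, ValueError):
    """The analysis design cannot support the request (e.g. an arm with < 2 patients)."""
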