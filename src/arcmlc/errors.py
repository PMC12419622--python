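"""Exception hierarchy.

All toolkit errors derive from :class:`ArcMlcError` so that callers (and the
CLI) can map them onto exit codes: input/contract problems exit with 2,
undefined-metric conditions with 3.
"""


class ArcMlcError(Exception):
    """Base class for all toolkit errors."""


class InputError(ArcMlcError):
    """Invalid input data or arguments (CLI exit code 2)."""


class GridExtentError(InputError):
    """A structure or operation does not fit inside the voxel grid."""


class MarginClipError(GridExtentError):
    """A margin expansion would be truncated at the grid boundary."""


class MalformedPlanError(InputError):
    """A plan file violates a structural invariant (e.g. crossed leaves)."""


class UnsupportedPlanError(InputError):
    """A plan file lacks required content (e.g. no MLC device)."""


class FormatVersionError(InputError):
    """A serialized file declares an unknown format version."""


class GeometryError(InputError):
    """Projection geometry is degenerate (e.g. point behind the source)."""


class ConfigError(InputError):
    """A specification/config object is internally inconsistent."""


class MetricUndefinedError(ArcMlcError):
    """A metric has no defined value for the given inputs (CLI exit code 3)."""
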