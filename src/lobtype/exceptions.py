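"""Error taxonomy shared across the pipeline.

Each class maps to a distinct CLI exit code (see :mod:`lobtype.cli`).
"""


class LobtypeError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InvalidArgumentError(LobtypeError, ValueError):
    """A parameter violates an operation's stated preconditions."""

    exit_code = 2


class FormatError(LobtypeError, ValueError):
    """An input table does not conform to the documented dialect."""

    exit_code = 3


class DependencyError(LobtypeError, RuntimeError):
    """A pipeline stage is missing an upstream artifact."""

    exit_code = 4


class DegenerateGeometryError(LobtypeError, ValueError):
    """A point cloud is too degenerate for a frame or surface fit."""

    exit_code = 5


class DegenerateFeatureError(LobtypeError, ValueError):
    """A feature block has zero dispersion and cannot be normalized."""

    exit_code = 6
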