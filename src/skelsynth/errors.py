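"""Exception hierarchy for skelsynth."""


class SkelsynthError(Exception):
    """Base class for all skelsynth errors."""


class FormatError(SkelsynthError):
    """A model or motion file could not be parsed.

    Where possible the message names the offending line or field.
    """


class TopologyError(SkelsynthError):
    """The skeletal model's body/joint graph is not a tree rooted at ground."""


class IncompletePoseError(SkelsynthError):
    """A pose is missing values for one or more generalized coordinates."""


class DegenerateGeometryError(SkelsynthError):
    """Geometry too degenerate to operate on (zero-length bone, empty mesh, ...)."""
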