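"""Exception hierarchy shared by all pipeline stages.

Exit-code mapping used by the CLI: ``ValidationError`` -> 2, every other
``CetptrajError`` -> 3.
"""


class CetptrajError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(CetptrajError):
    """A structure or trajectory file violates its declared format."""


class EmptyInputError(CetptrajError):
    """A file or selection yielded zero sites/frames."""


class ShapeError(CetptrajError):
    """Frame/topology site-count mismatch or array-length mismatch."""


class GeometryError(CetptrajError):
    """Degenerate or unrealizable geometry (zero vector, coincident COMs...)."""


class BrokenMoleculeError(GeometryError):
    """A bonded site pair is implausibly far apart, indicating a molecule
    split across periodic boundaries; inputs must be whole molecules."""


class ValidationError(CetptrajError):
    """A configuration value failed schema validation before any computation."""
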