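"""Exception hierarchy for the plantmir pipeline.

Every error raised by the package derives from :class:`PlantmirError`, so
callers (and the CLI) can distinguish data problems from programming bugs.
"""


class PlantmirError(Exception):
    """Base class for all plantmir errors."""


class AmbiguityError(PlantmirError):
    """A sequence contains IUPAC ambiguity codes (N, R, Y, ...).

    Ambiguous sequences are disqualified outright rather than masked: the
    control-qualification rules require candidates built from unambiguous
    residues only.
    """


class ParseError(PlantmirError):
    """A sequence file could not be parsed."""


class NoDuplexError(PlantmirError):
    """No candidate:star hybridization with negative energy exists."""


class WindowError(PlantmirError):
    """The requested search side cannot host a star partner.

    Raised when the context on the given side of the candidate is shorter
    than the candidate length plus the minimum loop gap.
    """


class StructureError(PlantmirError):
    """A dot-bracket string is unbalanced or malformed."""


class PoolExhaustedError(PlantmirError):
    """The EST pool cannot supply the requested number of negative controls."""


class EmptyDatasetError(PlantmirError):
    """A classifier was asked to train on an empty dataset."""


class SchemaError(PlantmirError):
    """Attribute names of a vector do not match the model's schema."""


class DegenerateTrainingError(PlantmirError):
    """A cross-validation fold's training set lacks one of the two classes."""
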