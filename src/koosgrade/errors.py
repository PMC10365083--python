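"""Exception hierarchy for the koosgrade package."""


class KoosGradeError(Exception):
    """Base class for all package errors."""


class LabelDecodingError(KoosGradeError):
    """A file opened as a label map contains non-integral values."""


class OrientationError(KoosGradeError):
    """Orientation metadata is missing, singular, or undecodable."""


class ParameterError(KoosGradeError):
    """An argument violates its contract (e.g. non-positive spacing)."""


class SchemeError(KoosGradeError):
    """A structure name or label integer is not part of the label scheme."""


class GeometryError(KoosGradeError):
    """Two volumes expected on a common grid do not match."""


class DegenerateInputError(KoosGradeError):
    """Input is empty or otherwise carries no usable signal."""


class StateError(KoosGradeError):
    """Operation applied to an object in the wrong state."""


class DegenerateTrainingError(KoosGradeError):
    """Training data cannot support a model (e.g. a single class)."""


class PhantomSpecError(KoosGradeError):
    """A phantom specification is geometrically invalid."""
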