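"""Exception hierarchy shared across fusewalk modules."""


class FuseWalkError(Exception):
    """Base class for all fusewalk errors."""


class MissingAnnotationError(FuseWalkError):
    """A required gene is absent from the domain-annotation table."""


class InconsistentInputError(FuseWalkError):
    """Inputs contradict each other (e.g. retained domain not annotated)."""


class InvalidInputError(FuseWalkError):
    """A value is outside its documented range or a file is malformed."""


class EmptySeedError(FuseWalkError):
    """No predicted partner survives; propagation cannot be seeded."""
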