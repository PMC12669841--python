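"""Exception types shared across romkit."""


class RomkitError(Exception):
    """Base class for all romkit errors."""


class InvalidInputError(RomkitError, ValueError):
    """An input violates a documented precondition."""


class OutOfDomainError(RomkitError):
    """A query point lies outside the interpolable interior of an SDF grid.

    Raised instead of clamping: silently clamping distance queries would
    corrupt the constraint landscape seen by the contact and ligament
    optimizers.
    """


class DegenerateFrameError(RomkitError):
    """A coordinate frame could not be constructed (collinear inputs)."""
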