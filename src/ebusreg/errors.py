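"""Exception hierarchy for ebusreg."""


class EbusRegError(Exception):
    """Base class for all ebusreg errors."""


class InvalidInputError(EbusRegError, ValueError):
    """An input violates a documented precondition (non-finite pose, bad window, ...)."""


class EmptyROIError(EbusRegError, ValueError):
    """An operation that requires a nonempty ROI mask received an empty one."""


class EmptyRegionError(EbusRegError, ValueError):
    """A histogram region contains no pixels."""


class DegenerateEntropyError(EbusRegError, ArithmeticError):
    """Joint entropy is zero (both images constant over the region), so the
    normalized mutual information cost is undefined."""


class NoWallFoundError(EbusRegError, RuntimeError):
    """A ray left the CT volume without crossing the airway-wall HU threshold."""


class SimplexConstructionError(EbusRegError, RuntimeError):
    """A simplex vertex could not be projected onto the airway wall."""


class InvalidSpecError(EbusRegError, ValueError):
    """A phantom specification is geometrically inconsistent."""
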