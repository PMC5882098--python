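"""Exception types shared across the package."""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but carries no usable signal
    (e.g. constant-intensity slide, empty probability map)."""


class InvalidDataError(ValueError):
    """A dataset violates a requirement of the algorithm
    (e.g. a single-class training set)."""


class InvalidArchitectureError(ValueError):
    """A network stage list collapses the spatial dimensions to zero."""


class CapacityError(RuntimeError):
    """Requested number of ROIs could not be placed.

    Attributes
    ----------
    n_placed : int
        How many ROIs were successfully placed before giving up.
    """

    def __init__(self, message: str, n_placed: int):
        super().__init__(message)
        self.n_placed = n_placed


class MissingLabelError(KeyError):
    """A patch references a patient id absent from the patient table."""


class ConfigDriftError(RuntimeError):
    """A partial run directory exists with a different configuration hash."""


class InvalidStateError(RuntimeError):
    """A pipeline verb was invoked before its required inputs exist."""
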