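"""Exception hierarchy shared across the pipeline stages."""


class CugScreenError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(CugScreenError, ValueError):
    """A caller-supplied parameter is out of its documented range."""


class InputError(CugScreenError, ValueError):
    """An input object (molecule, structure, grid) is malformed or empty."""


class DegenerateInputError(CugScreenError, ValueError):
    """Input is formally valid but has no usable signal (e.g. zero variance)."""


class CorrespondenceError(CugScreenError, ValueError):
    """Structures cannot be put into atom-by-atom correspondence."""


class DisconnectedNetworkError(CugScreenError, ValueError):
    """Elastic network falls apart into several components at the cutoff."""

    def __init__(self, message, components=None):
        super().__init__(message)
        self.components = components or []
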