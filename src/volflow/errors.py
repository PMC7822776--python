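"""Package-specific exceptions."""


class VolflowError(Exception):
    """Base class for all package errors."""


class DegenerateChannelError(VolflowError):
    """A channel of the initialization batch has zero standard deviation."""


class InitializationRequiredError(VolflowError):
    """Actnorm was applied before its data-dependent initialization."""


class NonInvertibleWeightError(VolflowError):
    """The 1x1x1 convolution weight matrix is (numerically) singular."""


class NumericalOverflowError(VolflowError):
    """A coupling network produced non-finite scale/shift values."""


class ShapeError(VolflowError):
    """An input volume or latent code has an incompatible shape."""


class TrainingDivergedError(VolflowError):
    """The training loss became non-finite.

    Carries the partial :class:`~volflow.train.TrainReport` up to the failing
    step in ``report`` and the failing step index in ``step``.
    """

    def __init__(self, message, report=None, step=None):
        super().__init__(message)
        self.report = report
        self.step = step
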