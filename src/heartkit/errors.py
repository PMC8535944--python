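"""Exception hierarchy for the heartkit pipeline.

Every stage raises a subclass of :class:`HeartkitError` so that the pipeline
driver can attribute a failure to a stage and an item id.
"""


class HeartkitError(Exception):
    """Base class for all heartkit errors."""


class DecodeError(HeartkitError):
    """Audio file could not be read or decoded."""


class EmptySignal(HeartkitError):
    """Zero-length audio where at least one sample is required."""


class SilentSignal(HeartkitError):
    """All-zero signal cannot be amplitude-normalized."""


class ManifestError(HeartkitError):
    """Malformed dataset manifest (unknown split, bad counts...)."""


class FilterSpecError(HeartkitError):
    """Invalid IIR filter specification for the given sample rate."""


class NumericalError(HeartkitError):
    """Numerical instability detected (unstable filter, overflow...)."""


class EmptyInput(HeartkitError):
    """An operation received an empty sequence."""


class DepthError(HeartkitError):
    """Signal too short for the requested wavelet decomposition depth."""


class EmptyEnvelope(HeartkitError):
    """Signal shorter than one envelope frame."""


class ConstantEnvelope(HeartkitError):
    """Zero-variance envelope cannot be standardized."""


class NoPeriodicity(HeartkitError):
    """No positive autocorrelation peak inside the physiological window."""


class ShapeError(HeartkitError):
    """Dimension mismatch between data and model parameters."""


class VarianceCollapse(HeartkitError):
    """A mixture component collapsed onto a point (variance below floor)."""


class StratificationError(HeartkitError):
    """A class has too few groups to fill the requested folds."""


class TrainingError(HeartkitError):
    """Degenerate training set (e.g. a single class)."""


class LabelError(HeartkitError):
    """Evaluation item carries a label unknown to the model."""


class ConfigError(HeartkitError):
    """Run-configuration document violates the schema."""

    def __init__(self, message: str, path: str = "$"):
        super().__init__(f"{path}: {message}")
        self.path = path
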