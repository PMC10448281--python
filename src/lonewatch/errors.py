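"""Exception hierarchy shared across the pipeline."""


class LonewatchError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LonewatchError):
    """Invalid configuration (cohort size, rates out of range, ...)."""


class ParameterError(LonewatchError):
    """A numeric parameter outside its admissible range."""


class DegenerateSignalError(LonewatchError):
    """A signal too degenerate to process (flat window, empty series, ...)."""


class UndersamplingError(ParameterError):
    """Sampling frequency too low for the cardiac band."""


class TrainingError(LonewatchError):
    """Quality-model training could not proceed."""


class BuildError(LonewatchError):
    """Dataset assembly failed (e.g. zero retained samples)."""


class MetricError(LonewatchError):
    """Evaluation metrics undefined for the given inputs."""
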