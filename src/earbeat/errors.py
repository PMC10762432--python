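"""Exception hierarchy for the earbeat pipeline."""


class EarbeatError(Exception):
    """Base class for all earbeat errors."""


class ParameterError(EarbeatError, ValueError):
    """Invalid model or algorithm parameters."""


class ConfigError(EarbeatError, ValueError):
    """Malformed pipeline configuration; message carries the key path."""


class FormatError(EarbeatError, ValueError):
    """Unreadable or inconsistent recording file."""


class SingularityError(EarbeatError, ValueError):
    """Field evaluation requested at (or too close to) the source location."""


class UndefinedMetricError(EarbeatError, ValueError):
    """A similarity metric is undefined for the given inputs."""
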