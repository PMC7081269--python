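"""Exception hierarchy shared across the package."""


class MlwalkError(Exception):
    """Base class for all mlwalk errors."""


class ConfigError(MlwalkError, ValueError):
    """Invalid configuration: bad parameter value, duplicate layer id, malformed manifest."""


class GeneLookupError(MlwalkError, KeyError):
    """A gene (or state) was requested that the queried structure does not contain."""

    def __str__(self) -> str:  # KeyError quotes its payload; keep the message readable
        return Exception.__str__(self)


class PipelineError(MlwalkError, RuntimeError):
    """A pipeline stage failed; message carries the stage name and offending entity."""
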