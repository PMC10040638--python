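"""Exception hierarchy shared across the pipeline."""


class CrcMicroError(Exception):
    """Base class for all package errors."""


class InputError(CrcMicroError):
    """Malformed or irreconcilable input tables."""


class ConfigurationError(CrcMicroError):
    """Invalid simulation or run configuration.

    ``errors`` carries the full list of individual problems so callers can
    report them all at once.
    """

    def __init__(self, errors):
        if isinstance(errors, str):
            errors = [errors]
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class PipelineError(CrcMicroError):
    """A pipeline stage failed; the message names the stage."""
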