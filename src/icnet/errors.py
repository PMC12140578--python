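"""Exception hierarchy shared across the pipeline."""


class IcnetError(Exception):
    """Base class for all package-specific errors."""


class InputError(IcnetError, ValueError):
    """Invalid data passed to an operation (wrong shape, band, sampling rate...)."""


class ConfigurationError(IcnetError, ValueError):
    """Invalid study/generator/atlas configuration (bad indices, duplicates...)."""


class DegenerateInputError(IcnetError, ValueError):
    """Numerically degenerate input, e.g. zero variance where a scale is needed."""
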