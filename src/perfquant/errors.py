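"""Exception hierarchy shared by all pipeline stages."""


class PerfquantError(Exception):
    """Base class for all errors raised by perfquant."""


class ConfigurationError(PerfquantError):
    """A run parameter is missing, out of range, or inconsistent."""


class DimensionError(PerfquantError):
    """Array shapes or image dimensions do not match what a stage requires."""
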