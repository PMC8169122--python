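"""Exception types shared across pulsefate."""


class PulsefateError(Exception):
    """Base class for all pulsefate errors."""


class ConfigurationError(PulsefateError):
    """A model/analysis parameter is invalid; the message names the field."""


class AllocationError(ConfigurationError):
    """A fate allocation is inconsistent with the cohort it is applied to."""


class FormatError(PulsefateError):
    """An input table or image does not have the expected layout."""
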