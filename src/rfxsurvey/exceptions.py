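"""Exception hierarchy shared across the pipeline."""


class RFXSurveyError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(RFXSurveyError):
    """A file could not be parsed (malformed FASTA, matrix, manifest...)."""


class ConfigError(RFXSurveyError):
    """A run-configuration value violates an invariant."""


class ParameterError(RFXSurveyError):
    """An argument to an operation is out of its documented range."""


class InputError(RFXSurveyError):
    """An input sequence or record is invalid (unknown residue, empty...)."""
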