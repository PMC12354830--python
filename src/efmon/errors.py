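"""Exception hierarchy shared across the pipeline."""


class EfmonError(Exception):
    """Base class for all package errors."""


class FormatError(EfmonError):
    """Input file violates the expected on-disk format."""


class ContractError(EfmonError):
    """A function precondition or shape contract was violated."""


class ConfigError(EfmonError):
    """Invalid or incomplete configuration."""


class DetectionError(EfmonError):
    """Signal too short or otherwise unsuitable for interference detection."""


class SplitLeakageError(EfmonError):
    """A sensor id appears in more than one of train/val/test."""
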