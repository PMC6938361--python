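"""Exception hierarchy for the eyeblink-conditioning scoring pipeline."""


class EbcError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EbcError):
    """Invalid parameter or configuration value; message names the violated constraint."""


class DegenerateTrialError(EbcError):
    """A trial whose baseline cannot be standardized (zero or non-finite baseline SD)."""


class ContractError(EbcError):
    """An operation was called outside its precondition."""


class DatasetError(EbcError):
    """Malformed, inconsistent or unreadable stored dataset."""
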