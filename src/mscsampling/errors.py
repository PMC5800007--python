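"""Exception hierarchy. Configuration errors (bad user input) are kept
distinct from compute-time input errors so the CLI can map them to exit codes."""


class MscSamplingError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MscSamplingError):
    """Invalid configuration or parameter choice."""


class InputError(MscSamplingError):
    """Invalid data passed to an operation."""


class UnitError(InputError):
    """Branch-length units do not match what the operation requires."""


class SamplingError(MscSamplingError):
    """An allele-assignment rule cannot be satisfied by the available samples."""


class SizingError(ConfigurationError):
    """A requested design (e.g. disjoint locus sets) exceeds the available pool."""


class NewickParseError(InputError):
    """Malformed Newick input; carries the character offset of the problem."""

    def __init__(self, message: str, offset: int = -1):
        super().__init__(message)
        self.offset = offset
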