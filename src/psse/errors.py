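"""Exception hierarchy for the psse package."""


class PsseError(Exception):
    """Base class for all psse-specific errors."""


class ParseError(PsseError):
    """A file could not be parsed (malformed FASTA, ss2, table ...)."""


class AlphabetError(PsseError):
    """A sequence contains a symbol outside the 3-state alphabet {H, E, C}."""


class FormatError(PsseError):
    """A structured file violates its format contract."""


class ConfigError(PsseError):
    """An invalid recipe / configuration was supplied."""


class DegenerateInputError(PsseError):
    """An operation's denominator or precondition is undefined for this input."""
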