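"""Exception hierarchy shared across the package."""


class LnchomexError(Exception):
    """Base class for all package errors."""


class FormatError(LnchomexError):
    """A file violates its declared format (malformed FASTA, MEME, BED, table schema...)."""


class InputError(LnchomexError):
    """Arguments are structurally valid but violate an operation's preconditions."""


class TrainingError(LnchomexError):
    """A classifier cannot be trained from the provided data."""


class ConfigError(LnchomexError):
    """Pipeline configuration is missing or inconsistent."""
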