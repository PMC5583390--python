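"""Exception hierarchy shared by all modules."""


class NrpairsError(Exception):
    """Base class for every error raised by this package."""


class InputError(NrpairsError, ValueError):
    """A record, token or file failed validation; the message names the position."""


class ConfigError(NrpairsError, ValueError):
    """An option value is outside its documented domain."""
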