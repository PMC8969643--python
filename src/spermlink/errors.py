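"""Exception hierarchy."""


class SpermLinkError(Exception):
    """Base class for all spermlink errors."""


class ParameterError(SpermLinkError, ValueError):
    """A parameter is outside its documented domain."""


class FormatError(SpermLinkError, ValueError):
    """An input file violates its format contract."""
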