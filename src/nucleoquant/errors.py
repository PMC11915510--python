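"""Exception hierarchy shared by all pipelines."""


class NucleoquantError(Exception):
    """Base class for all package errors."""


class ContractError(NucleoquantError):
    """An input violates a documented precondition (shape, range, cardinality)."""


class FormatError(NucleoquantError):
    """A file could not be read or does not match the declared layout."""


class PlacementError(NucleoquantError):
    """Synthetic objects cannot be placed inside the requested field of view."""
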