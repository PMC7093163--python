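"""Exception hierarchy for ESHRD input and contract violations."""


class EshrdError(Exception):
    """Base class for all ESHRD errors."""


class FormatError(EshrdError):
    """A file does not have the expected layout (header, columns)."""


class StructureError(EshrdError):
    """Input has the right format but an unusable shape (e.g. too few cell types)."""


class DataValueError(EshrdError, ValueError):
    """A cell of an input table violates its contract (negative fpkm, FDR > 1, ...)."""
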