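"""Exception hierarchy."""


class ParcfError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ParcfError, ValueError):
    """A parameter set violates its documented invariants."""


class UnitsError(ParcfError, ValueError):
    """Operands carry incompatible or unexpected units."""


class GridMismatchError(ParcfError, ValueError):
    """Rasters do not share a common lat/lon grid or period."""


class SpectrumFormatError(ParcfError, ValueError):
    """An external spectrum file is malformed."""
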