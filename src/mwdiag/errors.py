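"""Exception hierarchy shared across the pipeline stages."""


class MwdiagError(Exception):
    """Base class for all package errors."""


class ConfigError(MwdiagError):
    """Invalid run configuration (bad mode/model combination, bad budget, ...)."""

    exit_code = 2


class DataError(MwdiagError):
    """Invalid data passed between stages (length mismatch, single-class labels, ...)."""

    exit_code = 3


class GeometryError(DataError):
    """Physically impossible acquisition geometry (tumour outside breast, radius <= 0, ...)."""
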