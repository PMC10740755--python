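"""Exception hierarchy for the gfblup pipeline."""


class GfblupError(Exception):
    """Base class for all gfblup errors."""


class ConfigError(GfblupError, ValueError):
    """Invalid configuration value; message names the offending field."""


class PlinkFormatError(GfblupError, IOError):
    """Malformed PLINK binary file (bad magic bytes or mode byte)."""


class PlinkCorruptionError(GfblupError, IOError):
    """PLINK .bed payload size inconsistent with .bim/.fam counts."""


class EmptyPanelError(GfblupError, ValueError):
    """No SNPs remain after filtering or subsetting."""


class AlignmentError(GfblupError, ValueError):
    """Individual ids do not line up across objects."""

class DegenerateInputError(GfblupError, ValueError):
    """Mathematically degenerate input (e.g. both variances zero)."""


class IdentifiabilityError(GfblupError, ValueError):
    """Model variance components cannot be separated (e.g. identity kernel)."""


class ZeroVarianceError(GfblupError, ValueError):
    """Response or required column has no variance."""
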