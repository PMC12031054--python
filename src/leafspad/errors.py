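"""Exception hierarchy shared across the pipeline stages."""


class LeafSpadError(Exception):
    """Base class for all package-specific errors."""


class NoLeafFound(LeafSpadError):
    """Thresholding left no foreground pixel: the image has no detectable leaf."""


class EmptyROI(LeafSpadError):
    """An operation that needs leaf pixels received an empty mask."""


class DegenerateFit(LeafSpadError):
    """A model fit collapsed (e.g. every basis function pruned)."""


class AlignmentError(LeafSpadError):
    """Samples and labels cannot be paired one-to-one."""


class SchemaError(LeafSpadError):
    """Input columns/shape do not match what a fitted model expects."""


class ConfigError(LeafSpadError):
    """Invalid or inconsistent configuration."""
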