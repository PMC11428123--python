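"""Exception hierarchy for the xtalloy pipeline."""


class XtalloyError(Exception):
    """Base class for all package errors."""


class FormatError(XtalloyError):
    """A file could not be parsed (message names the offending item/line)."""


class UnsupportedFeatureError(XtalloyError):
    """Input uses a feature outside scope (e.g. partial occupancies)."""


class ArgumentError(XtalloyError, ValueError):
    """Invalid argument value."""


class GeometryError(XtalloyError):
    """Geometric construction failed (overlapping molecules, bad cell...)."""


class IncompatibilityError(XtalloyError):
    """Host and guest share no usable scaffold mapping."""


class AlignmentQualityError(XtalloyError):
    """Rigid superposition RMSD exceeded the acceptance threshold."""


class ConsistencyError(XtalloyError):
    """Internal bookkeeping invariant violated (counts, grids...)."""


class ClassificationError(XtalloyError):
    """A neighbor contact could not be assigned to a symmetry-unique type."""


class IncompleteTableError(XtalloyError):
    """An interaction table is missing required energy entries."""


class ConfigError(XtalloyError):
    """Invalid or incomplete run configuration."""


class MetricsUndefinedError(XtalloyError):
    """Morphology metrics requested on a degenerate (too small) crystal."""
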