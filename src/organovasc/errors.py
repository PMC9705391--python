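"""Typed exceptions shared across the package."""


class OrganovascError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OrganovascError):
    """A parameter set is internally inconsistent or infeasible."""


class QCError(OrganovascError):
    """Quality-control filtering produced an unusable (e.g. empty) result."""


class DegenerateNormalizationError(OrganovascError):
    """Anchor-based score normalization is undefined (coincident anchors)."""


class PipelineError(OrganovascError):
    """A pipeline stage failed; downstream stages were not run."""
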