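"""Exception hierarchy for the pipeline."""


class FlowQAError(Exception):
    """Base class for all package errors."""


class FCSParseError(FlowQAError):
    """Malformed FCS file (header offsets, TEXT segment, data segment)."""


class UnsupportedFeatureError(FlowQAError):
    """Valid FCS construct outside the supported subset (e.g. $MODE != L)."""


class TemplateError(FlowQAError):
    """Invalid gating template (unknown gate type, bad geometry, missing channel)."""


class MetadataError(FlowQAError):
    """Study metadata or task-definition table fails validation."""


class FormulaError(FlowQAError):
    """A QA formula does not match the y~x|g1*g2 grammar."""


class GatingError(FlowQAError):
    """Gating a sample failed (missing channel, unresolvable boolean operand)."""


class TransformError(FlowQAError):
    """Invalid transform parameters, singular spillover, or non-convergent inversion."""
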