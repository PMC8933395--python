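"""Exception hierarchy shared by all pipeline stages.

All domain errors derive from :class:`M7gFlowError` so callers (and the CLI)
can distinguish data problems (exit 1) from usage problems (exit 2).
"""


class M7gFlowError(Exception):
    """Base class for all m7gflow domain errors."""


class EmptyInputError(M7gFlowError):
    """An input collection or file that must be non-empty was empty."""


class FormatError(M7gFlowError):
    """A file or record did not conform to its expected format."""


class InputError(M7gFlowError):
    """Input values violate an operation's preconditions."""


class DegenerateInputError(M7gFlowError):
    """Input is structurally valid but degenerate (zero totals, no overlap...)."""


class ConfigError(M7gFlowError):
    """A simulation or run configuration is infeasible or inconsistent."""


class StructureError(M7gFlowError):
    """A secondary-structure annotation is unbalanced or inconsistent."""


class PatternError(M7gFlowError):
    """A degenerate-nucleotide motif pattern contains invalid characters."""
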