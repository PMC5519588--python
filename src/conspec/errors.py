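"""Exception hierarchy for the conspec pipeline.

The CLI maps these onto distinct exit codes so shell pipelines can
distinguish malformed input from contract violations and I/O failures.
"""


class ConspecError(Exception):
    """Base class for all conspec-specific errors."""


class ParseError(ConspecError):
    """Input text does not conform to the expected dialect."""


class PloidyError(ConspecError):
    """An individual does not carry exactly two phased alleles at a locus."""


class AlignmentError(ConspecError):
    """Sequences within a locus are not all the same length."""


class FormatError(ConspecError):
    """A record label does not follow the <individual>_<0|1> convention."""


class ValidationError(ConspecError):
    """An argument or configuration value violates its contract."""


class ConsistencyError(ConspecError):
    """Cross-object references disagree (unknown individual, mismatched sets)."""
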