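"""Exception types raised by targetasm."""


class TargetAsmError(Exception):
    """Base class for all package errors."""


class InputError(TargetAsmError):
    """A required input file is missing, empty, or malformed."""


class TargetValidationError(TargetAsmError):
    """A target sequence failed validation (too short or non-ACGT)."""


class DesignError(TargetAsmError):
    """A target-design request is inconsistent (bad context, alleles or arms)."""
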