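"""Small DNA string helpers used throughout the package."""

import re

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_NON_ACGTN = re.compile(r"[^ACGTN]")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_acgt(seq: str) -> bool:
    """True if ``seq`` is non-empty and contains only A, C, G, T."""
    return bool(seq) and not set(seq) - set("ACGT")


def sanitize_read(seq: str) -> str:
    """Uppercase a read and map every symbol outside {A,C,G,T,N} to N."""
    seq = seq.upper()
    return _NON_ACGTN.sub("N", seq)
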