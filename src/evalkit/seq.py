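"""Small sequence helpers used throughout the toolkit."""

from __future__ import annotations

import re

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Characters accepted in segment / haplotype sequences.
VALID_DNA = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


_NAT_SPLIT = re.compile(r"(\d+)")


def natural_key(s: str) -> tuple:
    """Sort key ordering embedded integers numerically ('s2' < 's10')."""
    return tuple(int(p) if p.isdigit() else p for p in _NAT_SPLIT.split(s))


def wrap_fasta(seq: str, width: int = 60) -> str:
    """Sequence body wrapped to fixed-width lines, trailing newline included."""
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width)) + "\n"
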