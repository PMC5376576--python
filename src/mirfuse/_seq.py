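"""Small sequence helpers shared across modules.

Sequences are stored as upper-case DNA (A/C/G/T); RNA input (U) is converted
on ingestion. Folding and duplex scoring treat T as U.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")

DNA = "ACGT"


def as_dna(seq: str) -> str:
    """Normalize a nucleotide string to upper-case DNA."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_nucleotide(seq: str) -> bool:
    return bool(seq) and all(c in "ACGT" for c in seq)


# Watson-Crick plus G:U wobble, on the DNA alphabet (T stands for U).
_CANPAIR = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _CANPAIR or (a, b) in _WOBBLE


def is_wobble(a: str, b: str) -> bool:
    return (a, b) in _WOBBLE


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(DNA), size=length))
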