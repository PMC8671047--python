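"""Small nucleotide-string helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T(/N) string."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, n: int) -> str:
    """Uniform random nucleotide string of length ``n``."""
    return "".join(rng.choice(list(BASES), size=n))


def hamming_prefix(a: str, b: str, tolerance: int = 0) -> int:
    """Length of the longest prefix of ``a`` matching ``b`` with at most
    ``tolerance`` mismatches, trimmed so the final compared base matches.

    Returns 0 when no prefix qualifies.
    """
    limit = min(len(a), len(b))
    mismatches = 0
    best = 0
    for i in range(limit):
        if a[i] == b[i]:
            best = i + 1
        else:
            mismatches += 1
            if mismatches > tolerance:
                break
    return best
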