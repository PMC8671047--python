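"""Independent brute-force oracles used to validate the fast implementation.

Everything here enumerates rather than indexes: bait matching scans every
prefix, prey placement enumerates every read split point and every
occurrence on both strands, and the pooled t-statistic is the closed form.
Nothing in this module shares code paths with the package internals it
checks (only coordinate bookkeeping from the locus object is reused).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy.special import stdtr

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def brute_prefix_len(read: str, ref: str) -> int:
    """Longest exact common prefix, by scanning every position."""
    n = 0
    for a, b in zip(read, ref):
        if a != b:
            break
        n += 1
    return n


def brute_suffix_occurrences(read, prey_ref, min_j=1, min_len=20):
    """Enumerate split points j (1-based, ascending) until some suffix
    read[j..] occurs in either strand of the prey; returns (j, occurrences)
    with occurrences as (strand, 0-based text offset) in the
    strand-oriented text. (None, []) when nothing qualifies."""
    texts = (("+", prey_ref), ("-", rc(prey_ref)))
    for j in range(min_j, len(read) + 2 - min_len):
        sub = read[j - 1 :]
        if len(sub) < min_len:
            break
        occs = []
        for strand, text in texts:
            start = 0
            while True:
                i = text.find(sub, start)
                if i == -1:
                    break
                occs.append((strand, i))
                start = i + 1
        if occs:
            return j, occs
    return None, []


@dataclass
class OracleCall:
    status: str
    bait_end_i: Optional[int] = None
    prey_pos: Optional[int] = None
    strand: Optional[str] = None
    mh_len: Optional[int] = None
    insertion_len: Optional[int] = None
    insertion_seq: str = ""


def oracle_call(read, locus, germline_threshold=10, min_len=20, min_j=1):
    """Reference junction call for an error-free read by split-point
    enumeration (exact matching, the caller's default tolerance)."""
    e_max = brute_prefix_len(read, locus.bait_ref)
    if e_max < len(locus.bait_primer):
        return OracleCall(status="unanchored", bait_end_i=e_max)
    if e_max >= locus.bait_break + germline_threshold:
        return OracleCall(status="germline", bait_end_i=e_max)
    j_min, occs = brute_suffix_occurrences(
        read, locus.prey_ref, min_j=min_j, min_len=min_len
    )
    if j_min is None:
        return OracleCall(status="unmapped", bait_end_i=e_max)
    if len(set(occs)) > 1:
        return OracleCall(status="ambiguous", bait_end_i=e_max)
    strand, toff = occs[0]
    mh = max(0, e_max - j_min + 1)
    ins_len = max(0, j_min - e_max - 1)
    ins_seq = read[e_max : j_min - 1] if ins_len else ""
    width = locus.prey_region.width
    if strand == "+":
        first = locus.prey_region.start + toff
        pos = first + mh
    else:
        first = locus.prey_region.start + (width - 1 - toff)
        pos = first - mh
    return OracleCall(
        status="junction",
        bait_end_i=e_max,
        prey_pos=pos,
        strand=strand,
        mh_len=mh,
        insertion_len=ins_len,
        insertion_seq=ins_seq,
    )


def brute_realized_mh(read, locus, strand, emit_offset, emit_read_pos):
    """Maximal exact overlap at a constructed junction, by enumeration:
    extend bait forward over every prefix, prey backward over every
    position, from full knowledge of the construction."""
    e_max = brute_prefix_len(read, locus.bait_ref)
    text = locus.prey_ref if strand == "+" else rc(locus.prey_ref)
    j = emit_read_pos
    while j > 1:
        toff = emit_offset + (j - 1) - emit_read_pos
        if toff < 0 or read[j - 2] != text[toff]:
            break
        j -= 1
    return max(0, e_max - j + 1)


def pooled_t_closed_form(a, b):
    """Student's pooled-variance two-sample t and two-sided p, written out
    from the textbook formula (p via the t CDF, not any t-test routine)."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    dof = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / dof
    t = (ma - mb) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * stdtr(dof, -abs(t))
    return t, p


def brute_kmer_scan(text, kmer):
    """All 0-based occurrences of ``kmer`` in ``text`` by full scan."""
    return [i for i in range(len(text) - len(kmer) + 1) if text[i : i + len(kmer)] == kmer]
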