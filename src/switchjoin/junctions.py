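"""Junction calling: bait anchoring, germline filtering, prey mapping and
microhomology/insertion resolution.

A read is processed in four stages. (1) Its prefix is matched against the
bait reference; reads that do not cover the full bait primer are
*unanchored*. (2) Reads whose bait match extends at least ``G`` bases past
the programmed break are *germline* — the in-silico analog of the AflII
blocking step that removes unbroken genomic fragments in the wet protocol.
(3) The remainder of the read is mapped against both strands of the prey
reference (exact k-mer seeds, maximal extension); no acceptable match means
*unmapped*, a tie between distinct loci means *ambiguous*. (4) The bait and
prey assignments are reconciled at the junction: overlap between the
maximal bait prefix and the maximal prey extension is microhomology,
a gap between them is an untemplated insertion (mutually exclusive by
construction). Junction coordinates follow the maximal-bait-extension
convention: the reported prey position is the first base past the
microhomology, i.e. the first base uniquely attributable to the prey side.

Exact-key deduplication — identical (prey position, strand, bait end) —
marks PCR duplicates; the offset-based criterion of the original HTGTS
pipeline lives in prior work and this exact-key rule is a stated
approximation of it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO

from ._dna import hamming_prefix, revcomp
from .refmodel import LocusMap

STATUSES = ("junction", "germline", "unmapped", "ambiguous", "duplicate", "unanchored")

TABLE_COLUMNS = [
    "read_id",
    "status",
    "bait_end_i",
    "prey_chrom",
    "prey_pos",
    "strand",
    "mh_len",
    "insertion_len",
    "insertion_seq",
]


@dataclass(frozen=True)
class BaitMatch:
    """Longest (tolerance-bounded) prefix match of a read against the bait."""

    match_len: int
    crosses_break: bool
    anchored: bool
    read_id: Optional[str] = None


@dataclass(frozen=True)
class PreyAlignment:
    """A candidate placement of the read's prey segment.

    ``read_start_j`` is the 1-based read position where the prey match
    begins (it may reach back inside the bait match — that overlap is the
    microhomology); ``prey_pos`` is the locus coordinate of the first
    prey-assigned base, in the locus-forward frame.
    """

    read_start_j: int
    prey_pos: int
    strand: str
    match_len: int
    mismatches: int


@dataclass
class CallParams:
    """Caller knobs.

    germline_threshold : bases past the bait break that flag a germline read
    tolerance : mismatches allowed in bait/prey matching (junction-adjacent
        bases are exact whenever tolerance is 0, the default)
    min_len : minimum prey match length
    min_j : smallest read position where a prey match may start
    """

    germline_threshold: int = 10
    tolerance: int = 0
    min_len: int = 20
    min_j: int = 1


@dataclass
class JunctionRecord:
    read_id: str
    status: str
    bait_end_i: Optional[int] = None
    prey_chrom: Optional[str] = None
    prey_pos: Optional[int] = None
    strand: Optional[str] = None
    mh_len: Optional[int] = None
    insertion_len: Optional[int] = None
    insertion_seq: str = ""

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


def match_bait(
    read: str,
    locus: LocusMap,
    germline_threshold: int = 10,
    tolerance: int = 0,
    read_id: Optional[str] = None,
) -> BaitMatch:
    """Anchor a read on the bait reference.

    ``match_len`` is the longest prefix of the read equal to the bait
    reference with at most ``tolerance`` mismatches (trimmed to end on a
    matching base). The read is anchored when the match covers the full
    bait primer; it crosses the break (germline) when the match extends at
    least ``germline_threshold`` bases past the programmed break.
    """
    if not read:
        raise ValueError("read is empty")
    match_len = hamming_prefix(read, locus.bait_ref, tolerance)
    anchored = match_len >= len(locus.bait_primer)
    crosses = match_len >= locus.bait_break + germline_threshold
    return BaitMatch(
        match_len=match_len, crosses_break=crosses, anchored=anchored, read_id=read_id
    )


class PreyIndex:
    """Exact k-mer index over both strands of the prey reference.

    Seed length is chosen so that, by pigeonhole, every match of length
    >= ``min_len`` with <= ``tolerance`` mismatches contains at least one
    exact seed; seed-and-extend is therefore complete for the matches
    :func:`map_prey` promises to find.
    """

    def __init__(self, locus: LocusMap, min_len: int = 20, tolerance: int = 0):
        self.locus = locus
        k = (min_len - tolerance) // (tolerance + 1)
        self.k = max(6, min(16, k))
        if self.k > min_len:
            self.k = min_len
        self.texts = {"+": locus.prey_ref, "-": revcomp(locus.prey_ref)}
        self._index: dict[str, list[tuple[str, int]]] = {}
        for strand, text in self.texts.items():
            for off in range(len(text) - self.k + 1):
                self._index.setdefault(text[off : off + self.k], []).append(
                    (strand, off)
                )

    def seeds(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])

    def coord(self, strand: str, text_offset: int) -> int:
        """Locus coordinate of a 0-based offset in the strand-oriented text."""
        if strand == "+":
            return self.locus.prey_coord(text_offset)
        return self.locus.prey_region.end - text_offset


def _extend(read: str, text: str, i: int, j: int, direction: int, budget: int):
    """Greedy gapless extension from (i, j); mismatches are only committed
    when a later matching base follows them. Returns (length, used)."""
    length = 0
    used = 0
    pending = 0
    n_read, n_text = len(read), len(text)
    while 0 <= i < n_read and 0 <= j < n_text:
        if read[i] == text[j]:
            length += pending + 1
            used += pending
            budget -= pending
            pending = 0
        else:
            if pending + 1 > budget:
                break
            pending += 1
        i += direction
        j += direction
    return length, used


def map_prey(
    read: str,
    min_j: int,
    locus: LocusMap,
    tolerance: int = 0,
    min_len: int = 20,
    index: Optional[PreyIndex] = None,
) -> list[PreyAlignment]:
    """All maximal placements of a read suffix on the prey reference.

    Scans both strands for the longest block ``read[j..]`` (1-based
    ``j >= min_j``) matching with at most ``tolerance`` mismatches and
    length at least ``min_len``. Candidates are ranked by match length
    (descending), mismatches (ascending), then leftmost prey coordinate.
    An empty list means unmapped.
    """
    if min_j < 1:
        raise ValueError("min_j must be >= 1")
    if index is None:
        index = PreyIndex(locus, min_len=min_len, tolerance=tolerance)
    k = index.k
    best: dict[tuple[str, int, int], PreyAlignment] = {}
    seen_diag: dict[tuple[str, int], int] = {}
    for p in range(min_j - 1, len(read) - k + 1):
        kmer = read[p : p + k]
        for strand, off in index.seeds(kmer):
            diag = off - p
            # at tolerance 0 every seed on a diagonal extends to the same
            # maximal block; skip repeats cheaply
            if tolerance == 0 and seen_diag.get((strand, diag)) is not None:
                continue
            seen_diag[(strand, diag)] = p
            text = index.texts[strand]
            len_r, used_r = _extend(read, text, p + k, off + k, +1, tolerance)
            len_l, used_l = _extend(
                read, text, p - 1, off - 1, -1, tolerance - used_r
            )
            j0 = p - len_l  # 0-based read start of the block
            if j0 < min_j - 1:
                # trim the left extension so the block honours min_j
                len_l = p - (min_j - 1)
                j0 = min_j - 1
            total = k + len_r + len_l
            if total < min_len:
                continue
            tstart = off - len_l
            pos = index.coord(strand, tstart)
            key = (strand, tstart, j0)
            aln = PreyAlignment(
                read_start_j=j0 + 1,
                prey_pos=pos,
                strand=strand,
                match_len=total,
                mismatches=used_r + used_l,
            )
            prev = best.get(key)
            if prev is None or (aln.match_len, -aln.mismatches) > (
                prev.match_len,
                -prev.mismatches,
            ):
                best[key] = aln
    return sorted(
        best.values(),
        key=lambda a: (-a.match_len, a.mismatches, a.prey_pos, a.strand),
    )


def resolve_junction(
    bait: BaitMatch,
    prey: PreyAlignment,
    read: str,
    locus: LocusMap,
    read_id: Optional[str] = None,
) -> JunctionRecord:
    """Reconcile bait and prey assignments at the junction.

    Overlap between the maximal bait prefix (``bait_end_i``) and the prey
    match start is microhomology; a gap is an untemplated insertion. The
    reported prey coordinate is advanced past the microhomology bases
    (maximal-bait-extension convention), so it names the first base
    uniquely attributable to the prey side.
    """
    if not bait.anchored:
        raise ValueError("bait is not anchored; cannot resolve a junction")
    if prey.read_start_j <= 0:
        raise ValueError("prey read_start_j must be positive")
    bait_end_i = bait.match_len
    mh_len = max(0, bait_end_i - prey.read_start_j + 1)
    insertion_len = max(0, prey.read_start_j - bait_end_i - 1)
    insertion_seq = read[bait_end_i : prey.read_start_j - 1] if insertion_len else ""
    if prey.strand == "+":
        prey_pos = prey.prey_pos + mh_len
    else:
        prey_pos = prey.prey_pos - mh_len
    return JunctionRecord(
        read_id=read_id if read_id is not None else (bait.read_id or ""),
        status="junction",
        bait_end_i=bait_end_i,
        prey_chrom=locus.prey_region.chrom,
        prey_pos=prey_pos,
        strand=prey.strand,
        mh_len=mh_len,
        insertion_len=insertion_len,
        insertion_seq=insertion_seq,
    )


def deduplicate(records: Sequence[JunctionRecord]) -> list[JunctionRecord]:
    """Mark exact-key PCR duplicates.

    Junction-status records sharing ``(prey_pos, strand, bait_end_i)``
    beyond the first (smallest ``read_id``) are re-labelled ``duplicate``.
    Other statuses pass through untouched. Deterministic.
    """
    groups: dict[tuple, list[JunctionRecord]] = {}
    for rec in records:
        if rec.status == "junction":
            groups.setdefault((rec.prey_pos, rec.strand, rec.bait_end_i), []).append(
                rec
            )
    out = list(records)
    keep_ids = {min(g, key=lambda r: r.read_id).read_id for g in groups.values()}
    for i, rec in enumerate(out):
        if rec.status == "junction" and rec.read_id not in keep_ids:
            out[i] = dataclasses.replace(rec, status="duplicate")
    return out


def call_reads(
    reads: Iterable[tuple[str, str]],
    locus: LocusMap,
    params: Optional[CallParams] = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Call every read; returns the junction table and status counts.

    Every input read appears exactly once with exactly one status, so the
    status counts always sum to the number of reads.
    """
    if params is None:
        params = CallParams()
    index = PreyIndex(locus, min_len=params.min_len, tolerance=params.tolerance)
    records: list[JunctionRecord] = []
    for read_id, seq in reads:
        bait = match_bait(
            seq,
            locus,
            germline_threshold=params.germline_threshold,
            tolerance=params.tolerance,
            read_id=read_id,
        )
        if not bait.anchored:
            records.append(JunctionRecord(read_id=read_id, status="unanchored",
                                          bait_end_i=bait.match_len))
            continue
        if bait.crosses_break:
            records.append(JunctionRecord(read_id=read_id, status="germline",
                                          bait_end_i=bait.match_len))
            continue
        cands = map_prey(
            seq,
            params.min_j,
            locus,
            tolerance=params.tolerance,
            min_len=params.min_len,
            index=index,
        )
        if not cands:
            records.append(JunctionRecord(read_id=read_id, status="unmapped",
                                          bait_end_i=bait.match_len))
            continue
        top = cands[0]
        tie = [
            c
            for c in cands
            if (c.match_len, c.mismatches) == (top.match_len, top.mismatches)
            and (c.strand, c.prey_pos) != (top.strand, top.prey_pos)
        ]
        if tie:
            records.append(JunctionRecord(read_id=read_id, status="ambiguous",
                                          bait_end_i=bait.match_len))
            continue
        records.append(resolve_junction(bait, top, seq, locus, read_id=read_id))
    records = deduplicate(records)
    df = records_to_frame(records)
    counts = {s: int((df["status"] == s).sum()) for s in STATUSES}
    return df, counts


def records_to_frame(records: Sequence[JunctionRecord]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    return df


def call_library(
    fastq: Union[str, Path],
    locus: LocusMap,
    params: Optional[CallParams] = None,
    out_tsv: Optional[Union[str, Path]] = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Call a FASTQ library; optionally write the junction TSV."""
    reads = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(fastq), "fastq")]
    df, counts = call_reads(reads, locus, params)
    if out_tsv is not None:
        write_junction_table(df, out_tsv, locus)
    return df, counts


def write_junction_table(
    df: pd.DataFrame, path: Union[str, Path], locus: LocusMap
) -> Path:
    """Write a junction TSV with the locus coordinates echoed in headers."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# switchjoin junction table\n")
        fh.write(f"# window={locus.window_signature()}\n")
        w = locus.core_acceptor
        fh.write(f"# core_acceptor={w.chrom}:{w.start}-{w.end}\n")
        w = locus.distal_acceptor
        fh.write(f"# distal_acceptor={w.chrom}:{w.start}-{w.end}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="")
    return path


def read_junction_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a junction TSV, recovering header metadata into ``df.attrs``."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            stripped = line[1:].strip()
            if "=" in stripped:
                key, value = stripped.split("=", 1)
                meta[key.strip()] = value.strip()
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"insertion_seq": str})
    df["insertion_seq"] = df["insertion_seq"].fillna("")
    df.attrs.update(meta)
    return df


def to_bed(df: pd.DataFrame, path: Union[str, Path]) -> Path:
    """Export junction positions as BED (0-based half-open: subtract 1 from
    the start only)."""
    path = Path(path)
    junc = df[df["status"] == "junction"]
    with open(path, "w") as fh:
        for _, row in junc.iterrows():
            pos = int(row["prey_pos"])
            fh.write(
                f"{row['prey_chrom']}\t{pos - 1}\t{pos}\t{row['read_id']}\t"
                f"{int(row['mh_len'])}\t{row['strand']}\n"
            )
    return path
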