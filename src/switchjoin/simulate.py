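"""Generative model of HTGTS-style class-switch junction libraries.

Each synthetic read mimics a LAM-PCR product: a fixed Smu bait prefix up to
the programmed bait break, followed (for junction reads) by an optional
untemplated insertion and then acceptor (Salpha/Calpha) sequence captured in
either orientation, truncated to the read length and subjected to uniform
substitution error. Germline contaminant reads simply continue along the
bait reference past the break, emulating the fragments the wet protocol
removes by AflII blocking.

The two pathway presets encode the qualitative contrast between classical
non-homologous end joining and alternative end joining: A-EJ uses longer
acceptor-side resection (joins pushed toward Calpha), a microhomology prior
peaked at 1-5 bp, and a larger inverted-capture fraction. Resection lengths
are geometric (one-parameter, memoryless); acceptor break positions are
normal around the core-Salpha midpoint, clamped into the analysis window.

Ground truth distinguishes the *planted* microhomology (what the sampler
aimed for) from the *realized* microhomology — the maximal exact overlap at
the constructed junction, which can exceed the planted value when flanking
bases coincide. Callers are judged against the realized value, and the
canonical junction coordinate follows the maximal-bait-extension convention
used by the calling module.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._dna import BASES, random_dna, revcomp
from .refmodel import LocusMap, default_locus

TRUTH_COLUMNS = [
    "read_id",
    "is_germline",
    "is_duplicate_of",
    "bait_end_pos",
    "acceptor_break_pos",
    "resection_len",
    "prey_strand",
    "prey_join_pos",
    "planted_mh",
    "realized_mh",
    "insertion_seq",
    "realized_insertion_len",
    "bait_end_canonical",
    "read_start_canonical",
    "prey_seg_len",
]


@dataclass(frozen=True)
class PathwayPreset:
    """Repair-pathway parameterisation of the junction sampler.

    resection_mean : mean acceptor-side resected bases (geometric on 0,1,2,...)
    mh_prior : categorical prior over target microhomology lengths
    insertion_prob : probability of an untemplated insertion (then MH target 0)
    ins_max : maximum insertion length (uniform 1..ins_max)
    inversion_prob : probability the join is captured in inverted orientation
    break_spread : SD (bp) of the acceptor break around the core midpoint
    """

    name: str
    resection_mean: float
    mh_prior: dict[int, float]
    insertion_prob: float
    inversion_prob: float
    break_spread: float
    ins_max: int = 3

    def __post_init__(self) -> None:
        total = sum(self.mh_prior.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mh_prior sums to {total}, expected 1")
        if any(k < 0 for k in self.mh_prior):
            raise ValueError("mh_prior keys must be non-negative")
        for label, p in (
            ("insertion_prob", self.insertion_prob),
            ("inversion_prob", self.inversion_prob),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{label} outside [0, 1]")
        if self.resection_mean < 0:
            raise ValueError("resection_mean must be >= 0")
        if self.break_spread < 0:
            raise ValueError("break_spread must be >= 0")


#: Default presets. These are modeling choices expressing the expected
#: qualitative contrast (A-EJ: more resection, more MH, more inversions),
#: not measurements.
PRESETS: dict[str, PathwayPreset] = {
    "cnhej": PathwayPreset(
        name="cnhej",
        resection_mean=150.0,
        mh_prior={0: 0.45, 1: 0.30, 2: 0.15, 3: 0.07, 4: 0.03},
        insertion_prob=0.08,
        inversion_prob=0.10,
        break_spread=600.0,
    ),
    "aej": PathwayPreset(
        name="aej",
        resection_mean=1200.0,
        mh_prior={0: 0.05, 1: 0.20, 2: 0.25, 3: 0.20, 4: 0.15, 5: 0.15},
        insertion_prob=0.04,
        inversion_prob=0.25,
        break_spread=600.0,
    ),
}


@dataclass
class SimulationConfig:
    """One synthetic library: locus, pathway preset and noise knobs."""

    preset: PathwayPreset
    n_reads: int
    seed: int
    locus: LocusMap = field(default_factory=default_locus)
    read_length: int = 100
    germline_fraction: float = 0.15
    duplicate_rate: float = 0.3
    error_rate: float = 0.001
    mh_search_window: int = 200

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        for label, frac in (
            ("germline_fraction", self.germline_fraction),
            ("error_rate", self.error_rate),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{label} outside [0, 1]")
        if self.duplicate_rate < 0:
            raise ValueError("duplicate_rate must be >= 0")
        if self.read_length <= len(self.locus.bait_primer) + 10:
            raise ValueError("read_length must exceed bait primer length + 10")
        if self.read_length > len(self.locus.bait_ref):
            raise ValueError(
                "read_length exceeds bait_ref length; germline reads cannot "
                "be synthesised"
            )
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class GroundTruthRecord:
    """Per-read simulated truth (canonical fields follow the
    maximal-bait-extension convention)."""

    read_id: str
    is_germline: bool
    is_duplicate_of: Optional[str] = None
    bait_end_pos: Optional[int] = None
    acceptor_break_pos: Optional[int] = None
    resection_len: Optional[int] = None
    prey_strand: Optional[str] = None
    prey_join_pos: Optional[int] = None
    planted_mh: Optional[int] = None
    realized_mh: Optional[int] = None
    insertion_seq: str = ""
    realized_insertion_len: Optional[int] = None
    bait_end_canonical: Optional[int] = None
    read_start_canonical: Optional[int] = None
    prey_seg_len: Optional[int] = None


def sample_break(
    preset: PathwayPreset, locus: LocusMap, rng: np.random.Generator
) -> int:
    """Acceptor break position: normal around the core-Salpha midpoint with
    SD ``break_spread``, rounded and clamped into the analysis window."""
    mid = locus.core_acceptor.midpoint
    if preset.break_spread == 0:
        return mid
    pos = int(round(rng.normal(mid, preset.break_spread)))
    w = locus.analysis_window
    return min(max(pos, w.start), w.end)


def sample_resection(preset: PathwayPreset, rng: np.random.Generator) -> int:
    """Resected bases on the acceptor side: geometric on {0,1,2,...} with
    mean ``resection_mean``."""
    m = preset.resection_mean
    if m <= 0:
        return 0
    p = 1.0 / (m + 1.0)
    return int(rng.geometric(p)) - 1


def anneal_join(
    bait_end_seq: str,
    acceptor_seq: str,
    target_mh: int,
    search_window: int,
    rng: Optional[np.random.Generator] = None,
    anchor: int = 0,
) -> tuple[int, int]:
    """Place a join with a target microhomology in ``acceptor_seq``.

    Scans within ``search_window`` bases of ``anchor`` (a 0-based offset,
    the resected position) for an exact occurrence of the terminal
    ``target_mh``-mer of ``bait_end_seq``; on failure the target is
    decremented and the scan repeated, down to a blunt join at the anchor.
    The nearest occurrence wins, ties breaking toward the smaller offset,
    so the placement is deterministic; ``rng`` is accepted for interface
    symmetry but unused.

    Returns ``(join_offset, planted_mh)`` where ``join_offset`` is the
    0-based offset in ``acceptor_seq`` of the planted microhomology (or of
    the blunt join when ``planted_mh`` is 0).
    """
    if not acceptor_seq:
        raise ValueError("acceptor_seq is empty")
    if target_mh < 0:
        raise ValueError("target_mh must be >= 0")
    anchor = min(max(anchor, 0), len(acceptor_seq) - 1)
    for m in range(target_mh, 0, -1):
        if m > len(bait_end_seq):
            continue
        kmer = bait_end_seq[-m:]
        lo = max(0, anchor - search_window)
        hi = min(len(acceptor_seq) - m, anchor + search_window)
        best = None
        start = lo
        while True:
            idx = acceptor_seq.find(kmer, start, hi + m)
            if idx == -1 or idx > hi:
                break
            dist = abs(idx - anchor)
            if best is None or dist < best[0]:
                best = (dist, idx)
            start = idx + 1
        if best is not None:
            return best[1], m
    return anchor, 0


def _canonical_junction(
    read_core: str,
    locus: LocusMap,
    strand: str,
    emit_offset: int,
    emit_read_pos: int,
) -> tuple[int, int, int, int, Optional[int]]:
    """Canonicalise a constructed junction read (pre-error).

    ``emit_offset`` is the 0-based offset in the strand-oriented acceptor
    text of the first emitted prey base, which sits at 1-based read
    position ``emit_read_pos``. Returns (bait_end_canonical,
    read_start_canonical, realized_mh, realized_insertion_len,
    prey_join_pos).
    """
    bait_ref = locus.bait_ref
    text = locus.prey_ref if strand == "+" else revcomp(locus.prey_ref)

    limit = min(len(read_core), len(bait_ref))
    e_max = 0
    while e_max < limit and read_core[e_max] == bait_ref[e_max]:
        e_max += 1

    # extend the prey assignment backward from the emitted segment start
    j_min = emit_read_pos
    while j_min > 1:
        toff = emit_offset + (j_min - 1) - emit_read_pos
        if toff < 0 or read_core[j_min - 2] != text[toff]:
            break
        j_min -= 1

    realized_mh = max(0, e_max - j_min + 1)
    realized_ins = max(0, j_min - e_max - 1)

    q_star = max(e_max + 1, j_min)
    toff_star = emit_offset + q_star - emit_read_pos
    if q_star <= len(read_core) and 0 <= toff_star < len(text):
        if strand == "+":
            join_pos = locus.prey_coord(toff_star)
        else:
            join_pos = locus.prey_region.end - toff_star
    else:
        join_pos = None
    return e_max, j_min, realized_mh, realized_ins, join_pos


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0 or not seq:
        return seq
    hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
    if hits.size == 0:
        return seq
    out = list(seq)
    for i in hits:
        alternatives = [b for b in BASES if b != out[i]]
        out[i] = alternatives[int(rng.integers(3))]
    return "".join(out)


def _build_junction(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[str, GroundTruthRecord]:
    """One junction read core (pre-error) plus its truth record."""
    locus = config.locus
    preset = config.preset
    e = locus.bait_break
    bait_part = locus.bait_ref[:e]

    strand = "-" if rng.random() < preset.inversion_prob else "+"
    break_pos = sample_break(preset, locus, rng)
    resection = sample_resection(preset, rng)
    w = locus.analysis_window
    join0 = min(max(break_pos + resection, w.start), w.end)

    if rng.random() < preset.insertion_prob:
        ins_len = int(rng.integers(1, preset.ins_max + 1))
        insertion = random_dna(rng, ins_len)
        target_mh = 0
    else:
        insertion = ""
        keys = sorted(preset.mh_prior)
        probs = np.array([preset.mh_prior[k] for k in keys], dtype=float)
        target_mh = int(rng.choice(keys, p=probs / probs.sum()))

    if strand == "+":
        text = locus.prey_ref
        anchor = locus.prey_offset(join0)
    else:
        text = revcomp(locus.prey_ref)
        anchor = locus.prey_region.end - join0

    join_off, planted = anneal_join(
        bait_part, text, target_mh, config.mh_search_window, anchor=anchor
    )
    emit_offset = join_off + planted
    tail_budget = config.read_length - e - len(insertion)
    emitted = text[emit_offset : emit_offset + max(tail_budget, 0)]
    read_core = bait_part + insertion + emitted
    emit_read_pos = e + len(insertion) + 1

    e_can, j_can, mh, ins_real, join_pos = _canonical_junction(
        read_core, locus, strand, emit_offset, emit_read_pos
    )
    truth = GroundTruthRecord(
        read_id="",
        is_germline=False,
        bait_end_pos=e,
        acceptor_break_pos=break_pos,
        resection_len=resection,
        prey_strand=strand,
        prey_join_pos=join_pos,
        planted_mh=planted,
        realized_mh=mh,
        insertion_seq=insertion,
        realized_insertion_len=ins_real,
        bait_end_canonical=e_can,
        read_start_canonical=j_can,
        prey_seg_len=len(emitted),
    )
    return read_core, truth


def synthesize_read(
    truth: GroundTruthRecord,
    locus: LocusMap,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> str:
    """Materialise the sequence of a read from its truth record.

    Germline reads are the bait reference continuing uninterrupted past the
    break; junction reads are bait prefix + insertion + strand-oriented
    prey from the planted junction. Substitution error is applied per
    ``config.error_rate``.
    """
    if truth.is_germline:
        core = locus.bait_ref[: config.read_length]
    elif truth.prey_join_pos is None:
        core = locus.bait_ref[: truth.bait_end_pos] + truth.insertion_seq
    else:
        e = truth.bait_end_pos
        text = locus.prey_ref if truth.prey_strand == "+" else revcomp(locus.prey_ref)
        # offset of the first *unique* prey base (past realized MH) is the
        # canonical join; rebuild from the canonical read start instead
        toff_start = (
            locus.prey_offset(truth.prey_join_pos)
            if truth.prey_strand == "+"
            else locus.prey_region.end - truth.prey_join_pos
        )
        # canonical join corresponds to read position max(e_can+1, j_can)
        q_star = max(truth.bait_end_canonical + 1, truth.read_start_canonical)
        emit_offset = toff_start - (q_star - (e + len(truth.insertion_seq) + 1))
        tail_budget = config.read_length - e - len(truth.insertion_seq)
        emitted = text[emit_offset : emit_offset + max(tail_budget, 0)]
        core = locus.bait_ref[:e] + truth.insertion_seq + emitted
    return _apply_errors(core, config.error_rate, rng)


def simulate_reads(
    config: SimulationConfig,
) -> tuple[list[tuple[str, str]], list[GroundTruthRecord]]:
    """Generate a library in memory.

    Returns ``(reads, truths)`` where ``reads`` is a list of
    ``(read_id, sequence)``. Exactly ``round(germline_fraction * n_reads)``
    of the ``n_reads`` unique reads are germline; each unique junction read
    additionally receives Poisson(``duplicate_rate``) duplicate copies with
    independently applied sequencing error.
    """
    rng = np.random.default_rng(config.seed)
    locus = config.locus
    n = config.n_reads
    n_germline = int(round(config.germline_fraction * n))

    flags = np.zeros(n, dtype=bool)
    flags[:n_germline] = True
    rng.shuffle(flags)

    reads: list[tuple[str, str]] = []
    truths: list[GroundTruthRecord] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"r{counter:06d}"

    germline_core = locus.bait_ref[: config.read_length]
    for is_germline in flags:
        if is_germline:
            rid = next_id()
            seq = _apply_errors(germline_core, config.error_rate, rng)
            reads.append((rid, seq))
            truths.append(GroundTruthRecord(read_id=rid, is_germline=True))
            continue
        core, truth = _build_junction(config, rng)
        rid = next_id()
        truth.read_id = rid
        reads.append((rid, _apply_errors(core, config.error_rate, rng)))
        truths.append(truth)
        n_dup = int(rng.poisson(config.duplicate_rate)) if config.duplicate_rate else 0
        for _ in range(n_dup):
            dup_id = next_id()
            dup_truth = dataclasses.replace(
                truth, read_id=dup_id, is_duplicate_of=rid
            )
            reads.append((dup_id, _apply_errors(core, config.error_rate, rng)))
            truths.append(dup_truth)
    return reads, truths


def truth_frame(truths: Sequence[GroundTruthRecord]) -> pd.DataFrame:
    rows = [dataclasses.asdict(t) for t in truths]
    df = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return df


def simulate_library(
    config: SimulationConfig,
    fastq_path: Union[str, Path],
    truth_path: Union[str, Path],
) -> tuple[Path, Path]:
    """Write a synthetic library: FASTQ (constant Q40) + ground-truth TSV.

    Identical configs (same seed) produce byte-identical outputs.
    """
    fastq_path = Path(fastq_path)
    truth_path = Path(truth_path)
    reads, truths = simulate_reads(config)
    records = []
    for rid, seq in reads:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
    with open(fastq_path, "w") as fh:
        SeqIO.write(records, fh, "fastq")
    df = truth_frame(truths)
    df.to_csv(truth_path, sep="\t", index=False, na_rep="")
    return fastq_path, truth_path
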