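"""Locus geometry for switch-junction analysis.

The analysis is anchored on an IgH-like locus laid out in a locus-local
*forward* frame: forward means reading from the Smu donor switch region
through the Salpha acceptor toward Calpha (telomere to centromere).
``GenomicInterval.strand_sense`` records how that frame maps onto the
reference plus strand (the mouse IgH locus sits on reference minus, so the
bundled default uses ``reverse``); all coordinates here are 1-based
inclusive in the locus-forward frame.

The default acceptor window is a 20-kb region centered on core Salpha
(Chr12:114491001-114511000) tiled by 200-bp bins into 100 bins. Because no
public genome build is being re-aligned here, the bundled reference
sequences are synthetic stand-ins of the correct widths, generated once
from a fixed seed; the coordinates are locus-local labels attached to them,
not live genome coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml
from Bio import SeqIO

from ._dna import random_dna

#: 5' Smu bait primer used to anchor every read.
DEFAULT_BAIT_PRIMER = "CAGACCTGGGAATGTATGGT"

#: Default 20-kb acceptor analysis window centered on core Salpha.
DEFAULT_WINDOW = ("chr12", 114_491_001, 114_511_000)

DEFAULT_BIN_WIDTH = 200

#: Seed used once to materialise the synthetic stand-in reference sequences.
_REFERENCE_SEED = 912_662


class LocusValidationError(ValueError):
    """Raised when a locus description violates its geometric invariants."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive interval on a named chromosome.

    ``strand_sense`` records whether locus-forward equals reference-plus
    (``forward``) or reference-minus (``reverse``); it is bookkeeping only
    and never changes coordinate arithmetic, which lives entirely in the
    locus-forward frame.
    """

    chrom: str
    start: int
    end: int
    strand_sense: str = "forward"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise LocusValidationError(
                f"interval start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise LocusValidationError("coordinates are 1-based; start < 1")
        if self.strand_sense not in ("forward", "reverse"):
            raise LocusValidationError(
                f"strand_sense must be forward/reverse, got {self.strand_sense!r}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and not (
            self.end < other.start or other.end < self.start
        )

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class LocusMap:
    """Everything the pipeline needs to know about the locus.

    ``bait_ref`` covers primer -> programmed bait break -> germline
    continuation; ``prey_ref`` spans ``prey_region`` (by default identical
    to ``analysis_window``) in the locus-forward orientation.
    """

    bait_primer: str
    bait_break: int
    bait_ref: str
    prey_ref: str
    prey_region: GenomicInterval
    core_acceptor: GenomicInterval
    distal_acceptor: GenomicInterval
    analysis_window: GenomicInterval
    bin_width: int = DEFAULT_BIN_WIDTH

    def __post_init__(self) -> None:
        if not self.bait_ref.startswith(self.bait_primer):
            raise LocusValidationError("bait_primer is not a prefix of bait_ref")
        if not (len(self.bait_primer) <= self.bait_break <= len(self.bait_ref)):
            raise LocusValidationError(
                "bait_break must lie between the primer end and the end of bait_ref"
            )
        if len(self.prey_ref) != self.prey_region.width:
            raise LocusValidationError(
                f"prey_ref length {len(self.prey_ref)} != prey_region width "
                f"{self.prey_region.width}"
            )
        for name, iv in (
            ("core_acceptor", self.core_acceptor),
            ("distal_acceptor", self.distal_acceptor),
        ):
            if not self.analysis_window.contains_interval(iv):
                raise LocusValidationError(
                    f"{name} is not contained in the analysis window"
                )
        if self.core_acceptor.overlaps(self.distal_acceptor):
            raise LocusValidationError("core and distal acceptor intervals overlap")
        if not self.prey_region.contains_interval(self.analysis_window):
            raise LocusValidationError("analysis window exceeds prey reference span")
        if self.bin_width <= 0:
            raise LocusValidationError("bin_width must be positive")
        if self.analysis_window.width % self.bin_width != 0:
            raise LocusValidationError(
                f"bin_width {self.bin_width} does not divide window width "
                f"{self.analysis_window.width}"
            )

    @property
    def n_bins(self) -> int:
        return self.analysis_window.width // self.bin_width

    def prey_offset(self, pos: int) -> int:
        """0-based offset into ``prey_ref`` for a locus coordinate."""
        return pos - self.prey_region.start

    def prey_coord(self, offset: int) -> int:
        """Locus coordinate of a 0-based ``prey_ref`` offset."""
        return self.prey_region.start + offset

    def window_signature(self) -> str:
        w = self.analysis_window
        return f"{w.chrom}:{w.start}-{w.end}/bin{self.bin_width}"


def locate(pos: int, locus: LocusMap) -> str:
    """Label a locus coordinate: ``core`` | ``distal`` | ``window_other`` |
    ``outside``. Core/distal take precedence over window_other."""
    if locus.core_acceptor.contains(pos):
        return "core"
    if locus.distal_acceptor.contains(pos):
        return "distal"
    if locus.analysis_window.contains(pos):
        return "window_other"
    return "outside"


def bin_index(pos: int, window: GenomicInterval, bin_width: int) -> Optional[int]:
    """1-based bin number of ``pos`` in ``window``, or ``None`` outside.

    bin = floor((pos - window.start) / bin_width) + 1
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not window.contains(pos):
        return None
    return (pos - window.start) // bin_width + 1


def _default_sequences() -> tuple[str, str]:
    """Synthetic bait/prey stand-in references, deterministic across runs."""
    rng = np.random.default_rng(_REFERENCE_SEED)
    primer = DEFAULT_BAIT_PRIMER
    bait_ref = primer + random_dna(rng, 150 - len(primer))
    width = DEFAULT_WINDOW[2] - DEFAULT_WINDOW[1] + 1
    prey_ref = random_dna(rng, width)
    return bait_ref, prey_ref


def default_locus() -> LocusMap:
    """The bundled default locus.

    20-kb window Chr12:114491001-114511000 in 200-bp bins; core acceptor =
    central 4 kb of the window; distal acceptor = everything downstream of
    core through the window end (the Calpha-side long-resection zone);
    bait break 45 bases into a 150-base bait reference.
    """
    chrom, wstart, wend = DEFAULT_WINDOW
    bait_ref, prey_ref = _default_sequences()
    window = GenomicInterval(chrom, wstart, wend, strand_sense="reverse")
    mid_lo = wstart + window.width // 2 - 2000  # 114499001
    core = GenomicInterval(chrom, mid_lo, mid_lo + 3999, "reverse")
    distal = GenomicInterval(chrom, core.end + 1, wend, "reverse")
    return LocusMap(
        bait_primer=DEFAULT_BAIT_PRIMER,
        bait_break=45,
        bait_ref=bait_ref,
        prey_ref=prey_ref,
        prey_region=window,
        core_acceptor=core,
        distal_acceptor=distal,
        analysis_window=window,
        bin_width=DEFAULT_BIN_WIDTH,
    )


def _interval_from_config(value, default: Optional[GenomicInterval]) -> Optional[GenomicInterval]:
    if value is None:
        return default
    sense = default.strand_sense if default is not None else "forward"
    chrom_default = default.chrom if default is not None else "chr12"
    if isinstance(value, (list, tuple)) and len(value) == 3:
        chrom, start, end = value
        return GenomicInterval(str(chrom), int(start), int(end), sense)
    if isinstance(value, dict):
        return GenomicInterval(
            str(value.get("chrom", chrom_default)),
            int(value["start"]),
            int(value["end"]),
            str(value.get("strand_sense", sense)),
        )
    raise LocusValidationError(f"cannot parse interval from {value!r}")


def _read_single_fasta(path: Union[str, Path]) -> str:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise LocusValidationError(
            f"expected exactly one FASTA record in {path}, found {len(records)}"
        )
    return str(records[0].seq).upper()


def load_locus(config: Union[None, str, Path, dict] = None) -> LocusMap:
    """Build a validated :class:`LocusMap` from a YAML config.

    ``config`` may be ``None`` (built-in defaults), a mapping, or a path to
    a YAML file. Recognised keys: ``bait_primer``, ``bait_break``,
    ``bait_ref`` / ``bait_fasta``, ``prey_ref`` / ``prey_fasta``,
    ``analysis_window``, ``prey_region``, ``core_acceptor``,
    ``distal_acceptor`` (each ``[chrom, start, end]`` or a mapping), and
    ``bin_width``. Unspecified keys fall back to the defaults.
    """
    if config is None:
        return default_locus()
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise LocusValidationError("locus config must be a mapping or a YAML path")

    base = default_locus()
    window = _interval_from_config(config.get("analysis_window"), base.analysis_window)
    prey_region = _interval_from_config(config.get("prey_region"), window)
    core = _interval_from_config(config.get("core_acceptor"), None if "analysis_window" in config else base.core_acceptor)
    distal = _interval_from_config(config.get("distal_acceptor"), None if "analysis_window" in config else base.distal_acceptor)
    if core is None or distal is None:
        raise LocusValidationError(
            "a custom analysis_window requires explicit core_acceptor and "
            "distal_acceptor intervals"
        )

    if "bait_fasta" in config:
        bait_ref = _read_single_fasta(config["bait_fasta"])
    else:
        bait_ref = str(config.get("bait_ref", base.bait_ref)).upper()
    if "prey_fasta" in config:
        prey_ref = _read_single_fasta(config["prey_fasta"])
    elif "prey_ref" in config:
        prey_ref = str(config["prey_ref"]).upper()
    elif prey_region.width == base.prey_region.width:
        prey_ref = base.prey_ref
    else:
        raise LocusValidationError(
            "a custom prey_region requires prey_ref or prey_fasta"
        )

    return LocusMap(
        bait_primer=str(config.get("bait_primer", base.bait_primer)).upper(),
        bait_break=int(config.get("bait_break", base.bait_break)),
        bait_ref=bait_ref,
        prey_ref=prey_ref,
        prey_region=prey_region,
        core_acceptor=core,
        distal_acceptor=distal,
        analysis_window=window,
        bin_width=int(config.get("bin_width", base.bin_width)),
    )
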