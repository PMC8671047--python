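"""Figure-level readouts from junction tables.

Orientation classification follows the productive-joining convention: a
prey segment read in the locus-forward (telomere-to-centromere, Smu toward
Calpha) orientation is a *deletional* junction; the opposite orientation is
*inversional*; junctions landing outside the analysis window are *other*.
Junctions whose prey coordinate falls in the distal (Calpha-side) acceptor
interval are long-resection junctions.

Derived statistics: per-bin deletion/inversion landscapes over the
analysis window, the deletion/inversion ratio, the long-resection
percentage (denominator: all in-window junctions, deletional plus
inversional), the microhomology spectrum (insertion-bearing junctions kept
as their own class by default, preserving the blunt/MH distinction), a
pooled-variance two-sample Student's t-test for replicate-level group
comparisons, and switching-efficiency normalizations (to scramble-control
means, or to the GFP+ fraction 24 h after transfection in the
Cas9-initiated assay).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .refmodel import GenomicInterval, LocusMap, bin_index, locate

INSERTION_CLASS = "insertion"


@dataclass
class BinnedLandscape:
    """Per-bin deletion/inversion junction counts over the analysis window."""

    window: GenomicInterval
    bin_width: int
    deletion_counts: np.ndarray
    inversion_counts: np.ndarray
    n_pooled_libraries: int = 1
    n_outside_window: int = 0

    @property
    def n_bins(self) -> int:
        return self.window.width // self.bin_width

    def to_frame(self) -> pd.DataFrame:
        starts = self.window.start + self.bin_width * np.arange(self.n_bins)
        return pd.DataFrame(
            {
                "bin": np.arange(1, self.n_bins + 1),
                "start": starts,
                "end": starts + self.bin_width - 1,
                "del_count": self.deletion_counts.astype(int),
                "inv_count": self.inversion_counts.astype(int),
            }
        )


@dataclass
class SummaryStats:
    """One library's (or pool's) junction summary."""

    n_junctions: int
    n_deletion: int
    n_inversion: int
    n_other: int
    del_inv_ratio: Optional[float]
    del_inv_ratio_defined: bool
    pct_long_resection: Optional[float]
    pct_window_of_total: Optional[float]
    mh_spectrum: dict

    def to_row(self) -> dict:
        row = {
            "n_junctions": self.n_junctions,
            "n_deletion": self.n_deletion,
            "n_inversion": self.n_inversion,
            "n_other": self.n_other,
            "del_inv_ratio": self.del_inv_ratio,
            "pct_long_resection": self.pct_long_resection,
            "pct_window_of_total": self.pct_window_of_total,
        }
        for k, v in self.mh_spectrum.items():
            row[f"mh_{k}"] = v
        return row


@dataclass
class CsrMeasurement:
    """A switching-efficiency measurement and its normalization."""

    sample_pct: float
    control_pcts: Sequence[float] = field(default_factory=list)
    gfp24_pct: Optional[float] = None
    normalized_pct: Optional[float] = None


def _junction_rows(table: pd.DataFrame) -> pd.DataFrame:
    return table[table["status"] == "junction"]


def classify_orientation(record, locus: LocusMap) -> str:
    """``deletion`` | ``inversion`` | ``other`` for one junction record.

    Accepts a JunctionRecord-like object or a table row (anything with
    ``status``, ``strand`` and ``prey_pos`` attributes/keys).
    """
    get = record.get if hasattr(record, "get") else lambda k: getattr(record, k)
    if get("status") != "junction":
        raise ValueError("orientation is defined only for junction-status records")
    pos = int(get("prey_pos"))
    if not locus.analysis_window.contains(pos):
        return "other"
    return "deletion" if get("strand") == "+" else "inversion"


def classify_table(table: pd.DataFrame, locus: LocusMap) -> pd.DataFrame:
    """Annotate junction rows with ``orientation`` and ``region`` columns."""
    out = table.copy()
    out["orientation"] = ""
    out["region"] = ""
    mask = out["status"] == "junction"
    if mask.any():
        pos = out.loc[mask, "prey_pos"].astype(int)
        inside = pos.map(locus.analysis_window.contains)
        strand = out.loc[mask, "strand"]
        orientation = np.where(
            ~inside, "other", np.where(strand == "+", "deletion", "inversion")
        )
        out.loc[mask, "orientation"] = orientation
        out.loc[mask, "region"] = pos.map(lambda p: locate(p, locus))
    out.attrs = dict(table.attrs)
    return out


def pool(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate junction tables from the same locus.

    Per-library read ids are preserved under a ``library`` provenance
    column; no cross-library deduplication is applied. Tables whose
    ``window`` metadata disagree cannot be pooled.
    """
    if not tables:
        raise ValueError("no tables to pool")
    windows = {t.attrs.get("window") for t in tables}
    if len(windows) > 1:
        raise ValueError(f"cannot pool tables with different windows: {windows}")
    parts = []
    for i, t in enumerate(tables):
        part = t.copy()
        if "library" not in part.columns:
            part.insert(0, "library", i + 1)
        parts.append(part)
    pooled = pd.concat(parts, ignore_index=True)
    pooled.attrs = dict(tables[0].attrs)
    pooled.attrs["n_pooled_libraries"] = len(tables)
    return pooled


def bin_landscape(table: pd.DataFrame, locus: LocusMap) -> BinnedLandscape:
    """Per-bin deletion/inversion counts; out-of-window junctions are
    excluded from the bins and counted separately."""
    n_bins = locus.n_bins
    dels = np.zeros(n_bins, dtype=int)
    invs = np.zeros(n_bins, dtype=int)
    outside = 0
    for _, row in _junction_rows(table).iterrows():
        pos = int(row["prey_pos"])
        b = bin_index(pos, locus.analysis_window, locus.bin_width)
        if b is None:
            outside += 1
            continue
        if row["strand"] == "+":
            dels[b - 1] += 1
        else:
            invs[b - 1] += 1
    return BinnedLandscape(
        window=locus.analysis_window,
        bin_width=locus.bin_width,
        deletion_counts=dels,
        inversion_counts=invs,
        n_pooled_libraries=int(table.attrs.get("n_pooled_libraries", 1)),
        n_outside_window=outside,
    )


def deletion_inversion_ratio(
    table: pd.DataFrame, locus: LocusMap
) -> tuple[Optional[float], bool]:
    """(ratio, defined): deletional / inversional junction counts in the
    analysis window; undefined (not an exception) when no inversions."""
    junc = _junction_rows(table)
    if junc.empty:
        return None, False
    pos = junc["prey_pos"].astype(int)
    inside = pos.map(locus.analysis_window.contains)
    n_del = int(((junc["strand"] == "+") & inside).sum())
    n_inv = int(((junc["strand"] == "-") & inside).sum())
    if n_inv == 0:
        return None, False
    return n_del / n_inv, True


def long_resection_fraction(
    table: pd.DataFrame, locus: LocusMap
) -> Optional[float]:
    """Percentage of in-window junctions whose prey coordinate lies in the
    distal (Calpha-side) acceptor; ``None`` when there are none in-window."""
    junc = _junction_rows(table)
    if junc.empty:
        return None
    pos = junc["prey_pos"].astype(int)
    inside = pos.map(locus.analysis_window.contains)
    n_window = int(inside.sum())
    if n_window == 0:
        return None
    n_distal = int(pos[inside].map(locus.distal_acceptor.contains).sum())
    return 100.0 * n_distal / n_window


def mh_spectrum(
    table: pd.DataFrame,
    cap: int = 10,
    insertions_as_own_class: bool = True,
) -> dict:
    """Microhomology-length proportions over junction-status records.

    Lengths above ``cap`` are pooled into ``cap``. Insertion-bearing
    junctions form their own class by default (preserving the blunt-vs-MH
    distinction); with ``insertions_as_own_class=False`` they are counted
    at MH 0. An empty table yields an empty dict.
    """
    junc = _junction_rows(table)
    if junc.empty:
        return {}
    spectrum: dict = {}
    n = len(junc)
    has_ins = junc["insertion_len"].fillna(0).astype(int) > 0
    mh = junc["mh_len"].fillna(0).astype(int).clip(upper=cap)
    if insertions_as_own_class:
        counted = mh[~has_ins]
        for m in range(cap + 1):
            spectrum[m] = int((counted == m).sum()) / n
        spectrum[INSERTION_CLASS] = int(has_ins.sum()) / n
    else:
        for m in range(cap + 1):
            spectrum[m] = int((mh == m).sum()) / n
    return spectrum


def summarize_table(
    table: pd.DataFrame, locus: LocusMap, mh_cap: int = 10
) -> SummaryStats:
    """All per-library summary statistics in one pass."""
    junc = _junction_rows(table)
    n_junc = len(junc)
    if n_junc:
        pos = junc["prey_pos"].astype(int)
        inside = pos.map(locus.analysis_window.contains)
        n_del = int(((junc["strand"] == "+") & inside).sum())
        n_inv = int(((junc["strand"] == "-") & inside).sum())
        n_other = int((~inside).sum())
        pct_window = 100.0 * (n_del + n_inv) / n_junc
    else:
        n_del = n_inv = n_other = 0
        pct_window = None
    ratio, defined = deletion_inversion_ratio(table, locus)
    return SummaryStats(
        n_junctions=n_junc,
        n_deletion=n_del,
        n_inversion=n_inv,
        n_other=n_other,
        del_inv_ratio=ratio,
        del_inv_ratio_defined=defined,
        pct_long_resection=long_resection_fraction(table, locus),
        pct_window_of_total=pct_window,
        mh_spectrum=mh_spectrum(table, cap=mh_cap),
    )


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: int
    infinite: bool = False


def compare_groups_ttest(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> TTestResult:
    """Two-sample Student's t-test (pooled variance, two-sided).

    Welch's unequal-variance variant is available behind ``welch``. Two
    identical zero-variance groups return t=0, p=1 by convention; two
    different zero-variance groups are flagged infinite.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    dof = len(a) + len(b) - 2
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, p=1.0, df=dof)
        return TTestResult(
            t=math.copysign(math.inf, a.mean() - b.mean()), p=0.0, df=dof,
            infinite=True,
        )
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue), df=dof)


def normalize_csr(sample_pct: float, control_pcts: Sequence[float]) -> float:
    """Switching efficiency as a percentage of the scramble-control mean."""
    controls = np.asarray(control_pcts, dtype=float)
    if controls.size == 0:
        raise ValueError("no control measurements")
    mean = controls.mean()
    if mean <= 0:
        raise ValueError("control mean must be positive")
    return 100.0 * float(sample_pct) / float(mean)


def normalize_cas9_csr(igx_pct: float, gfp24_pct: float) -> float:
    """Cas9-initiated switching normalized to the GFP+ fraction measured
    24 h after transfection."""
    if gfp24_pct <= 0:
        raise ValueError("gfp24_pct must be positive")
    return 100.0 * float(igx_pct) / float(gfp24_pct)


def write_landscape(
    landscape: BinnedLandscape, path, locus: LocusMap
):
    """Landscape TSV: bin, start, end, del_count, inv_count."""
    with open(path, "w") as fh:
        fh.write("# switchjoin landscape\n")
        fh.write(f"# window={locus.window_signature()}\n")
        fh.write(f"# n_pooled_libraries={landscape.n_pooled_libraries}\n")
        fh.write(f"# n_outside_window={landscape.n_outside_window}\n")
        landscape.to_frame().to_csv(fh, sep="\t", index=False)
    return path
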