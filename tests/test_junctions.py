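"""Junction calling: bait anchoring, prey mapping, MH/insertion resolution,
deduplication and whole-library conservation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import brute_prefix_len, oracle_call
from switchjoin.junctions import (
    BaitMatch,
    CallParams,
    JunctionRecord,
    PreyAlignment,
    call_library,
    call_reads,
    deduplicate,
    map_prey,
    match_bait,
    read_junction_table,
    records_to_frame,
    resolve_junction,
    to_bed,
    write_junction_table,
)
from switchjoin.simulate import PRESETS, SimulationConfig, simulate_library, simulate_reads, truth_frame


def _sim(n, seed, preset="aej", **kw):
    kw.setdefault("error_rate", 0.0)
    cfg = SimulationConfig(preset=PRESETS[preset], n_reads=n, seed=seed, **kw)
    return cfg, *simulate_reads(cfg)


def expected_statuses(truths, locus, params=CallParams()):
    """Status each read should receive, derived from the ground-truth
    canonical fields only (independent of the caller)."""
    expected = {}
    junction_keys = {}
    for t in truths:
        if t.is_germline:
            expected[t.read_id] = "germline"
            continue
        e = t.bait_end_canonical
        if e < len(locus.bait_primer):
            expected[t.read_id] = "unanchored"
        elif e >= locus.bait_break + params.germline_threshold:
            expected[t.read_id] = "germline"
        elif t.prey_join_pos is None or (
            len_match := (t.prey_seg_len + (t.bait_end_pos + len(t.insertion_seq)
                          + 1 - t.read_start_canonical))
        ) < params.min_len:
            expected[t.read_id] = "unmapped"
        else:
            expected[t.read_id] = "junction"
            key = (t.prey_join_pos, t.prey_strand, e)
            junction_keys.setdefault(key, []).append(t.read_id)
    for key, ids in junction_keys.items():
        for rid in sorted(ids)[1:]:
            expected[rid] = "duplicate"
    return expected


class TestMatchBait:
    def test_prefix_stops_at_the_junction(self, toy_bait_locus):
        bm = match_bait("AAAACCGGGG", toy_bait_locus, tolerance=0)
        assert bm.match_len == 6 == brute_prefix_len("AAAACCGGGG", "AAAACCTTTT")
        assert not bm.crosses_break
        assert bm.anchored

    def test_read_through_break_is_germline(self, toy_bait_locus):
        bm = match_bait("AAAACCTTTT", toy_bait_locus, germline_threshold=3)
        assert bm.match_len == 10
        assert bm.crosses_break

    def test_primer_absent_is_unanchored(self, toy_bait_locus):
        bm = match_bait("GGGGGGGG", toy_bait_locus)
        assert not bm.anchored
        assert bm.match_len == 0

    def test_tolerance_allows_internal_mismatch(self, toy_bait_locus):
        # one substitution inside the bait segment
        bm = match_bait("AAATCCGGGG", toy_bait_locus, tolerance=1)
        assert bm.match_len == 6
        assert match_bait("AAATCCGGGG", toy_bait_locus, tolerance=0).match_len == 3

    def test_empty_read_rejected(self, toy_bait_locus):
        with pytest.raises(ValueError):
            match_bait("", toy_bait_locus)


class TestMapPrey:
    def test_forward_suffix_found(self, toy_prey_locus):
        hits = map_prey("AAAACCGGGG", 1, toy_prey_locus, min_len=4)
        top = hits[0]
        assert top.read_start_j == 5
        assert top.strand == "+"
        assert top.prey_pos == 5  # CCGGGG starts at the 5th prey base
        assert top.match_len == 6

    def test_reverse_complement_suffix_found(self, toy_prey_locus):
        # prey[5..10] = CGGGG A? use revcomp of prey bases 5..10 (CCGGGG)
        read = "AAAA" + "CCCCGG"  # revcomp(CCGGGG) = CCCCGG
        hits = map_prey(read, 1, toy_prey_locus, min_len=4)
        assert any(h.strand == "-" for h in hits)
        top = [h for h in hits if h.strand == "-"][0]
        assert top.match_len == 6
        # first read base of the minus match sits at the highest coordinate
        assert top.prey_pos == 10

    def test_no_match_is_empty(self, toy_prey_locus):
        assert map_prey("AAAACAACTA", 1, toy_prey_locus, min_len=6) == []

    def test_min_len_respected(self, toy_prey_locus):
        assert map_prey("AAAACCGGGG", 1, toy_prey_locus, min_len=8) == []

    def test_agrees_with_split_enumeration_on_default_locus(self, locus):
        from oracles import brute_suffix_occurrences

        rng = np.random.default_rng(17)
        w = locus.analysis_window
        for _ in range(25):
            off = int(rng.integers(0, w.width - 60))
            seg = locus.prey_ref[off : off + 40]
            read = "AAAA" + seg
            hits = map_prey(read, 1, locus, min_len=20)
            j, occs = brute_suffix_occurrences(read, locus.prey_ref, min_len=20)
            assert hits and j is not None
            assert hits[0].read_start_j == j
            strand, toff = occs[0]
            width = locus.prey_region.width
            expected_pos = (
                locus.prey_coord(toff)
                if strand == "+"
                else locus.prey_coord(width - 1 - toff)
            )
            assert (hits[0].strand, hits[0].prey_pos) == (strand, expected_pos)


class TestResolveJunction:
    def test_two_base_microhomology(self, toy_prey_locus):
        read = "AAAACCGGGG"
        bait = match_bait(read, toy_prey_locus)  # matches AAAACC -> i=6
        assert bait.match_len == 6
        prey = map_prey(read, 1, toy_prey_locus, min_len=4)[0]
        rec = resolve_junction(bait, prey, read, toy_prey_locus)
        assert rec.mh_len == 2
        assert rec.insertion_len == 0
        # prey coordinate advanced past the two MH bases
        assert rec.prey_pos == prey.prey_pos + 2 == 7

    def test_blunt_join(self, toy_prey_locus):
        bait = BaitMatch(match_len=4, crosses_break=False, anchored=True)
        prey = PreyAlignment(read_start_j=5, prey_pos=5, strand="+",
                             match_len=6, mismatches=0)
        rec = resolve_junction(bait, prey, "AAAACCGGGG", toy_prey_locus)
        assert (rec.mh_len, rec.insertion_len) == (0, 0)
        assert rec.prey_pos == 5

    def test_untemplated_insertion(self, toy_prey_locus):
        read = "AAAATTGGGG"
        bait = match_bait(read, toy_prey_locus)
        assert bait.match_len == 4
        prey = PreyAlignment(read_start_j=7, prey_pos=7, strand="+",
                             match_len=4, mismatches=0)
        rec = resolve_junction(bait, prey, read, toy_prey_locus)
        assert rec.mh_len == 0
        assert rec.insertion_len == 2
        assert rec.insertion_seq == "TT"

    def test_mh_and_insertion_mutually_exclusive_by_construction(self):
        @given(i=st.integers(1, 50), j=st.integers(1, 50))
        @settings(max_examples=200, deadline=None)
        def check(i, j):
            mh = max(0, i - j + 1)
            ins = max(0, j - i - 1)
            assert mh * ins == 0
        check()

    def test_inconsistent_prey_rejected(self, toy_prey_locus):
        bait = BaitMatch(match_len=6, crosses_break=False, anchored=True)
        prey = PreyAlignment(read_start_j=0, prey_pos=5, strand="+",
                             match_len=6, mismatches=0)
        with pytest.raises(ValueError):
            resolve_junction(bait, prey, "AAAACCGGGG", toy_prey_locus)


class TestDeduplicate:
    def _rec(self, rid, pos=100, strand="+", bait_end=45):
        return JunctionRecord(read_id=rid, status="junction", bait_end_i=bait_end,
                              prey_chrom="chr12", prey_pos=pos, strand=strand,
                              mh_len=0, insertion_len=0)

    def test_identical_keys_marked_duplicate(self):
        out = deduplicate([self._rec("r2"), self._rec("r1")])
        statuses = {r.read_id: r.status for r in out}
        assert statuses == {"r1": "junction", "r2": "duplicate"}

    def test_one_bp_offset_keys_both_kept(self):
        out = deduplicate([self._rec("r1", pos=100), self._rec("r2", pos=101)])
        assert all(r.status == "junction" for r in out)

    def test_strand_is_part_of_the_key(self):
        out = deduplicate([self._rec("r1", strand="+"), self._rec("r2", strand="-")])
        assert all(r.status == "junction" for r in out)

    def test_empty_input(self):
        assert deduplicate([]) == []


class TestCallLibrary:
    def test_status_counts_match_ground_truth(self, locus):
        cfg, reads, truths = _sim(100, 71, germline_fraction=0.2, duplicate_rate=0.4)
        df, counts = call_reads(reads, locus)
        expected = expected_statuses(truths, locus)
        observed = dict(zip(df["read_id"], df["status"]))
        assert observed == expected
        assert sum(counts.values()) == len(reads)

    def test_truth_recovery_on_error_free_library(self, locus):
        """Called MH, insertion length, strand and canonical junction
        coordinate equal the simulator's realized truth for every
        non-duplicate junction read."""
        cfg, reads, truths = _sim(600, 73)
        df, _ = call_reads(reads, locus)
        truth = truth_frame(truths).set_index("read_id")
        junc = df[df["status"] == "junction"]
        assert len(junc) > 300
        for _, row in junc.iterrows():
            t = truth.loc[row["read_id"]]
            assert row["mh_len"] == t["realized_mh"]
            assert row["insertion_len"] == t["realized_insertion_len"]
            assert row["prey_pos"] == t["prey_join_pos"]
            assert row["strand"] == t["prey_strand"]

    def test_conservation_on_adversarial_inputs(self, locus):
        # all germline
        _, reads, _ = _sim(50, 75, germline_fraction=1.0)
        _, counts = call_reads(reads, locus)
        assert counts["germline"] == 50
        assert sum(counts.values()) == 50
        # all unanchored (primer absent)
        rng = np.random.default_rng(0)
        junk = [(f"x{i}", "".join(rng.choice(list("ACGT"), size=80))) for i in range(30)]
        _, counts = call_reads(junk, locus)
        assert counts["unanchored"] == 30
        # all unmapped: bait prefix + non-prey tail
        tail = "T" * 50
        unmapped = [(f"u{i}", locus.bait_ref[: locus.bait_break] + tail) for i in range(5)]
        _, counts = call_reads(unmapped, locus)
        assert counts["unmapped"] == 5
        # empty
        df, counts = call_reads([], locus)
        assert df.empty and sum(counts.values()) == 0

    def test_oracle_equivalence_sample(self, locus):
        """Fast junction calls agree exactly with the brute-force
        split-point enumeration oracle on error-free reads."""
        _, reads, _ = _sim(300, 77, germline_fraction=0.1, duplicate_rate=0.0)
        df, _ = call_reads(reads, locus)
        by_id = dict(reads)
        for _, row in df.iterrows():
            ref = oracle_call(by_id[row["read_id"]], locus)
            status = row["status"] if row["status"] != "duplicate" else "junction"
            assert status == ref.status
            if ref.status == "junction":
                assert int(row["bait_end_i"]) == ref.bait_end_i
                assert int(row["prey_pos"]) == ref.prey_pos
                assert row["strand"] == ref.strand
                assert int(row["mh_len"]) == ref.mh_len
                assert int(row["insertion_len"]) == ref.insertion_len

    def test_call_library_reads_fastq(self, locus, tmp_path):
        cfg = SimulationConfig(preset=PRESETS["cnhej"], n_reads=40, seed=81,
                               error_rate=0.0)
        fq, _ = simulate_library(cfg, tmp_path / "lib.fastq", tmp_path / "t.tsv")
        df, counts = call_library(fq, locus, out_tsv=tmp_path / "j.tsv")
        assert sum(counts.values()) == len(df)
        back = read_junction_table(tmp_path / "j.tsv")
        assert len(back) == len(df)
        assert back.attrs["window"] == locus.window_signature()


class TestTableIO:
    def test_bed_export_is_zero_based_half_open(self, locus, tmp_path):
        rec = JunctionRecord(read_id="r1", status="junction", bait_end_i=45,
                             prey_chrom="chr12", prey_pos=114_500_000,
                             strand="+", mh_len=2, insertion_len=0)
        df = records_to_frame([rec])
        path = to_bed(df, tmp_path / "j.bed")
        fields = path.read_text().strip().split("\t")
        assert fields[:3] == ["chr12", "114499999", "114500000"]
        assert fields[5] == "+"

    def test_roundtrip_preserves_values(self, locus, tmp_path):
        recs = [
            JunctionRecord(read_id="r1", status="junction", bait_end_i=45,
                           prey_chrom="chr12", prey_pos=114_500_000, strand="+",
                           mh_len=2, insertion_len=0),
            JunctionRecord(read_id="r2", status="germline", bait_end_i=90),
        ]
        df = records_to_frame(recs)
        write_junction_table(df, tmp_path / "t.tsv", locus)
        back = read_junction_table(tmp_path / "t.tsv")
        assert list(back["status"]) == ["junction", "germline"]
        assert back.loc[0, "prey_pos"] == 114_500_000
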