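# Methods

## Locus model and coordinate conventions

All arithmetic lives in a locus-local *forward* frame: forward means
reading Sμ → Sα → Cα (telomere to centromere), the direction in which a
deletional junction's prey segment is read. Coordinates are 1-based
inclusive throughout; the single exception is BED export, which converts
to 0-based half-open by subtracting 1 from the start only. The
`strand_sense` field records how the frame maps to the reference plus
strand (the mouse IgH locus lies on reference minus) but never changes any
arithmetic.

The default acceptor window is Chr12:114491001–114511000 (20 kb) with
200-bp bins (100 bins; bin = ⌊(pos − start)/200⌋ + 1). The core Sα
interval is the central 4 kb of the window and the distal (long-resection)
zone is everything downstream of the core through the window end; neither
boundary is a published value, so both are configurable. The bait
reference is 150 bases (the 20-base Sμ primer `CAGACCTGGGAATGTATGGT`, 25
further bait bases, the programmed break after base 45, then germline
continuation). Because no genome is re-aligned here, bait and prey
references are synthetic uniform-random sequences of the correct widths,
generated once from a fixed internal seed so every run sees the same
locus. Synthetic references lack the G-rich tandem repeats of real switch
regions; consequences are discussed under Limitations.

## Generative model

Each unique read is germline with probability `germline_fraction`
(deterministically `round(f·n)` reads, so small libraries hit the
configured proportion exactly); germline reads are the bait reference
continuing uninterrupted past the break, emulating the fragments AflII
blocking removes in the wet protocol. A junction read is built as:

1. **Break position** ~ Normal(core midpoint, `break_spread`), rounded and
   clamped to the window — breaks cluster in core Sα.
2. **Resection** ~ Geometric on {0, 1, 2, …} with mean `resection_mean`
   (one parameter, memoryless). Resection is modeled on the acceptor side
   only and shifts the join downstream toward Cα; this single knob
   reproduces the long-resection readout. Inverted captures use the same
   join coordinate, read toward the telomere.
3. **Orientation**: inverted with probability `inversion_prob`.
4. **Junction chemistry**: with probability `insertion_prob` an
   untemplated insert of 1–`ins_max` random bases (MH target forced to 0,
   keeping MH and insertion mutually exclusive); otherwise a target MH
   drawn from `mh_prior`. The planted MH is realised by scanning the
   strand-oriented acceptor sequence within ±`mh_search_window` (default
   200 bp) of the resected position for the bait end's terminal k-mer,
   decrementing the target until an occurrence exists (nearest occurrence
   wins; ties go downstream-deterministic). In uniform-random sequence a
   5-mer is found within ±200 bp only ~45% of the time, so the realised
   prior is slightly flatter than the nominal one — immaterial, because
   callers are judged against the *realized* MH, recomputed from the
   constructed sequence as the maximal exact overlap at the junction
   (flanking coincidences can exceed the planted value; the recorded
   canonical junction coordinate follows the same maximal-bait-extension
   convention the caller uses).
5. **Read synthesis**: bait prefix + insertion + prey, truncated to
   `read_length` (default 100 nt, constant Q40), then uniform substitution
   error at `error_rate`. Each unique junction read receives
   Poisson(`duplicate_rate`) duplicate copies with independently applied
   error. A single `numpy` Generator seeded from the mandatory config seed
   drives everything, so identical configs give byte-identical FASTQ/TSV.

Preset parameters (modeling choices expressing the expected qualitative
contrast, not measurements): `cnhej` — resection mean 150 bp, MH prior
peaked at 0–1, insertion 0.08, inversion 0.10; `aej` — resection mean
1,200 bp, MH prior peaked at 1–5 bp, insertion 0.04, inversion 0.25; both
use break spread 600 bp. Defaults elsewhere: germline fraction 0.15,
duplicate rate 0.3, error rate 0.001.

## Junction calling

Bait anchoring takes the longest read prefix matching the bait reference
with at most `tolerance` mismatches (trimmed to end on a matching base);
reads not covering the full primer are *unanchored*. A match extending at
least `germline_threshold` (default 10, tolerant of chance matches) bases
past the break marks the read *germline*. Prey mapping is an exact k-mer
seed-and-extend over both strands of the prey reference; the seed length
is chosen from `min_len` (default 20) and `tolerance` so that, by
pigeonhole, every qualifying match contains an exact seed — at the default
tolerance 0 the procedure is therefore exhaustive, and the test suite
holds it to 100% agreement with a brute-force oracle that enumerates every
read split point. Candidates rank by (length desc, mismatches asc,
leftmost coordinate); a tie between distinct loci is reported *ambiguous*,
never silently resolved. With maximal bait extension `i` and maximal prey
back-extension to read position `j`: `mh = max(0, i − j + 1)`,
`insertion = max(0, j − i − 1)` (their product is zero by construction),
and the reported coordinate is advanced past the MH bases so it names the
first base uniquely attributable to the prey. Deduplication marks records
sharing the exact key (prey position, strand, bait end) beyond the
first-by-read-id; the original HTGTS pipeline's offset-based criterion is
described in prior work, and this exact-key rule is a stated
approximation of it. Every read receives exactly one of six statuses
(junction, germline, unmapped, ambiguous, duplicate, unanchored), so
status counts always sum to the read total.

## Summaries and statistics

Orientation: deletional iff prey strand is locus-forward and the
coordinate is in-window; inversional for the reverse strand in-window;
*other* outside. The long-resection percentage uses all in-window
junctions (deletional + inversional) as its denominator — the published
denominator is not stated, so this self-consistent choice is ours. The MH
spectrum is reported over junction-status records with lengths above the
cap (default 10) pooled into the cap and insertion-bearing junctions kept
as a separate class by default, preserving the blunt (MH = 0) vs MH
distinction; folding them into MH 0 is a flag away. Pooling concatenates
tables (same window required) with library provenance and no
cross-library dedup; landscapes report raw per-bin counts, and per-library
proportions are reported rather than depth-normalized, since the
cross-library normalization of the original figures is unspecified.
Replicate comparisons use the pooled-variance two-sample Student's *t*
(two-sided), matching the stated analysis choice; Welch is available
behind a flag; no multiple-testing correction is applied. Degenerate
inputs follow explicit conventions: two identical zero-variance groups
give t = 0, p = 1; differing zero-variance groups are flagged infinite-t.
CSR normalizations are plain ratios ×100: to the scramble-control mean,
or to the GFP⁺ fraction at 24 h post-transfection for Cas9-initiated CSR.

## What the simulator does and does not emulate

Emulated: break clustering in core Sα, pathway-dependent resection,
MH-mediated vs blunt vs insertion-bearing joins, both orientations,
germline contaminants, PCR duplicates, uniform substitution error.
Not emulated: repetitive/G-rich switch-region sequence, amplification
bias, indel errors, quality-score structure, paired ends, adapters,
multi-junction (chimeric) reads, or a genome-wide prey space. Passing
tests therefore demonstrate the correctness of the junction arithmetic
and the internal consistency of the pipeline on this generative model —
not calling accuracy on real repetitive switch-region data, where
ambiguous placements and offset-tolerant deduplication matter far more.

## Numerical and design notes

- Exact-key dedup also collapses *coincidental* same-position junctions;
  with breaks concentrated in a few kb this is a visible fraction at
  n ≈ 10³–10⁴ and mirrors unique-junction accounting, but means junction
  counts are not read counts.
- At tolerance 0 a sequencing error near the junction truncates the bait
  or prey extension at the error base, which can misattribute a few prey
  bases as an apparent insertion; raising `tolerance` trades this against
  MH precision (the overlap bases must be exact for MH to mean anything).
  All accuracy guarantees are stated for error-free reads.
- Geometric resection was chosen as the simplest one-parameter family;
  any replacement must preserve the strict monotonicity of the
  long-resection fraction in the resection mean, which is asserted by
  test.
- Problem sizes used by the shipped checks — 1,000 reads for oracle
  equivalence, 10,000 for spectrum recovery, 5,000 per arm for the
  pathway contrast — are the package's chosen desk-scale study
  conditions; all are seeded and rerun from scratch by
  `scripts/acceptance.py`.

## Known limitations

Single acceptor window per run (no Sγ1/Sε multi-acceptor runs); no
genome-wide translocation discovery; figure-faithful graphics are out of
scope (numeric landscape tables are the output); preset parameters are
not calibrated to any published library, since quantitative resection and
MH distributions for those libraries are figure-encoded only.
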