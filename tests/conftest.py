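import pytest

from switchjoin.refmodel import GenomicInterval, LocusMap, default_locus


@pytest.fixture(scope="session")
def locus():
    """The bundled default locus (20-kb window, 200-bp bins)."""
    return default_locus()


@pytest.fixture()
def toy_bait_locus():
    """Tiny locus for bait-anchoring worked examples:
    bait AAAACC|TTTT with the break after base 6."""
    window = GenomicInterval("t", 1, 20)
    return LocusMap(
        bait_primer="AAAA",
        bait_break=6,
        bait_ref="AAAACCTTTT",
        prey_ref="ACGTACGTACGTACGTACGT",
        prey_region=window,
        core_acceptor=GenomicInterval("t", 5, 8),
        distal_acceptor=GenomicInterval("t", 9, 20),
        analysis_window=window,
        bin_width=5,
    )


@pytest.fixture()
def toy_prey_locus():
    """Tiny locus for prey-mapping worked examples: prey TTTTCCGGGGAAAA."""
    window = GenomicInterval("t", 1, 14)
    return LocusMap(
        bait_primer="AAAA",
        bait_break=4,
        bait_ref="AAAACCTTTTGGCA",
        prey_ref="TTTTCCGGGGAAAA",
        prey_region=window,
        core_acceptor=GenomicInterval("t", 5, 8),
        distal_acceptor=GenomicInterval("t", 9, 14),
        analysis_window=window,
        bin_width=7,
    )
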