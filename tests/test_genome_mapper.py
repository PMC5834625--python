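"""Peptide-to-genome mapping, locus grouping, event calls, ORF context."""

import pytest
from Bio.Seq import Seq

from ipaw.db_builder import (
    segments_to_peptides,
    six_frame_translate,
    subtract_known,
    known_peptide_index,
)
from ipaw.genome_mapper import (
    EventCall,
    PeptideLocus,
    TranscriptModel,
    classify_event,
    detect_multimapping,
    extract_and_translate,
    group_loci,
    map_to_genome,
    orf_context,
)


def _codon_encode(peptide):
    table = {
        "M": "ATG", "K": "AAA", "R": "CGT", "P": "CCT", "E": "GAA",
        "T": "ACT", "I": "ATT", "D": "GAT", "A": "GCT", "G": "GGT",
        "L": "CTT", "V": "GTT",
    }
    return "".join(table[aa] for aa in peptide)


def test_map_single_exon_plus():
    tx = TranscriptModel("t", "chr1", "+", ((100, 400),))
    locus = map_to_genome("MKRE", 0, tx)
    assert locus.blocks == ((100, 112),)


def test_map_across_junction():
    tx = TranscriptModel("t", "chr1", "+", ((100, 106), (200, 230)))
    locus = map_to_genome("MKRE", 0, tx)
    assert locus.blocks == ((100, 106), (200, 206))


def test_map_minus_strand_counts_from_exon_end():
    tx = TranscriptModel("t", "chr1", "-", ((100, 400),))
    locus = map_to_genome("MKRE", 0, tx)
    assert locus.blocks == ((388, 400),)
    assert locus.strand == "-"


def test_map_rejects_overlong_span():
    tx = TranscriptModel("t", "chr1", "+", ((0, 30),))
    with pytest.raises(ValueError):
        map_to_genome("MKRETTTTTTT", 0, tx)


def test_map_roundtrip_translation():
    pep = "MKRPETID"
    genome = {"chr1": "T" * 50 + _codon_encode(pep) + "A" * 50}
    tx = TranscriptModel("t", "chr1", "+", ((50, 50 + 3 * len(pep)),))
    locus = map_to_genome(pep, 0, tx)
    assert extract_and_translate(locus, genome) == pep
    # same peptide planted on the minus strand
    rc = str(Seq(_codon_encode(pep)).reverse_complement())
    genome2 = {"chr1": "T" * 50 + rc + "A" * 50}
    tx2 = TranscriptModel("t", "chr1", "-", ((50, 50 + 3 * len(pep)),))
    locus2 = map_to_genome(pep, 0, tx2)
    assert extract_and_translate(locus2, genome2) == pep


def test_multimapping_counts():
    index = {"AAAAAAAK": [1, 2], "CCCCCCCK": [1], "JUNCTIONK": []}
    assert detect_multimapping("AAAAAAAK", index) == 2
    assert detect_multimapping("CCCCCCCK", index) == 1
    assert detect_multimapping("JUNCTIONK", index) == 0


def _locus(chrom, start, end, strand="+"):
    n_aa = (end - start) // 3
    return PeptideLocus("A" * n_aa, chrom, strand, ((start, end),))


def test_group_loci_gap_rule():
    loci = [
        _locus("chr1", 700, 1000),
        _locus("chr1", 5000, 5300),
        _locus("chr1", 20000, 20300),
    ]
    groups = group_loci(loci, gap=10000)
    assert groups[0] == groups[1] != groups[2]


def test_group_loci_single_linkage_chain():
    loci = [
        _locus("chr1", 0, 300),
        _locus("chr1", 9000, 9300),
        _locus("chr1", 18000, 18300),
    ]
    assert len(set(group_loci(loci, gap=10000).values())) == 1


def test_group_loci_chromosomes_and_order_invariance():
    loci = [_locus("chr1", 0, 300), _locus("chr2", 0, 300)]
    assert len(set(group_loci(loci).values())) == 2
    a = [_locus("chr1", 0, 300), _locus("chr1", 5000, 5300)]
    fwd = group_loci(a)
    rev = group_loci(list(reversed(a)))
    assert set(fwd.values()) == set(rev.values())


def test_loci_non_increasing_in_gap():
    loci = [_locus("chr1", s, s + 300) for s in (0, 4000, 9000, 25000)]
    n = [len(set(group_loci(loci, gap=g).values())) for g in (100, 5000, 30000)]
    assert n == sorted(n, reverse=True)


def test_classify_events_on_toy_truth(toy_genome):
    """Recovered novel peptides classify into their planted categories."""
    known = known_peptide_index(toy_genome.proteins)
    retained, _ = subtract_known(
        segments_to_peptides(six_frame_translate(toy_genome.genome)), known
    )
    truth_category = {
        p: rec.category for rec in toy_genome.truth for p in rec.novel_peptides
    }
    assert truth_category
    seen = set()
    for pep in retained:
        locus = PeptideLocus(pep.sequence, pep.chrom, pep.strand, pep.blocks)
        call = classify_event(locus, toy_genome.annotation)
        expected = truth_category[pep.sequence]
        assert call.category == expected, (pep.sequence, call, expected)
        seen.add(expected)
    assert {"pseudogene", "ncRNA", "intergenic", "5'UTR", "AltORF"} <= seen


def test_classify_empty_annotation_is_intergenic():
    call = classify_event(_locus("chr1", 10, 40), [])
    assert call == EventCall("intergenic")


def test_orf_context_scans_upstream_starts():
    pep = "KETID"
    dna = "TAA" + "CTG" + _codon_encode("AG") + _codon_encode(pep) + "GGT" + "TGA"
    genome = {"chr1": "CCCC" + dna + "CCCC"}
    start = 4 + 9  # peptide begins after TAA CTG and two codons
    locus = PeptideLocus(pep, "chr1", "+", ((4 + 12, 4 + 12 + 15),))
    ctx = orf_context(locus, genome)
    codons = [c for _pos, c, _ctx in ctx.candidates]
    assert "CTG" in codons and "ATG" not in codons
    assert ctx.upstream_stop is not None
    assert ctx.downstream_stop is not None


def test_orf_context_stop_immediately_upstream():
    pep = "KETID"
    dna = "TAA" + _codon_encode(pep) + "TGA"
    genome = {"chr1": "C" * 6 + dna + "C" * 6}
    locus = PeptideLocus(pep, "chr1", "+", ((9, 24),))
    ctx = orf_context(locus, genome)
    assert ctx.candidates == ()
    assert ctx.upstream_stop == 6
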