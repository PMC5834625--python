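"""Database construction: six-frame translation, pI partitioning, SAAV sets."""

import pytest
from Bio.Seq import Seq

from ipaw.db_builder import (
    PartitionConfig,
    build_6ft_db,
    build_decoy_db,
    build_saav_peptides,
    collapse_il,
    fraction_windows,
    known_peptide_index,
    segments_to_peptides,
    six_frame_translate,
    subtract_known,
    three_frame_translate,
)
from ipaw.pi_model import predict_pi


def test_six_frame_basic_translation():
    segs = six_frame_translate({"c": "ATGAAACGTTAA"})
    frame1 = [s for s in segs if s.frame == 1]
    assert [s.sequence for s in frame1] == ["MKR"]
    assert frame1[0].genomic_start == 0 and frame1[0].genomic_end == 9


def test_six_frame_ambiguous_codon_is_x():
    segs = six_frame_translate({"c": "ATGNAAATGGAT"})
    frame1 = [s for s in segs if s.frame == 1][0]
    assert frame1.sequence[1] == "X"


def test_six_frame_counts_and_strands():
    segs = six_frame_translate({"c": "ATGAAACGTGGGTAA"})
    assert {s.frame for s in segs} <= set(range(1, 7))
    assert any(s.strand == "-" for s in segs)


def test_six_frame_roundtrip_on_toy_genome(toy_genome):
    """Extracting each peptide's genomic block and translating reproduces it."""
    peptides = segments_to_peptides(six_frame_translate(toy_genome.genome))
    assert peptides
    for pep in peptides:
        seq = "".join(
            toy_genome.genome[pep.chrom][s:e] for s, e in pep.blocks
        )
        if pep.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        assert str(Seq(seq).translate()) == pep.sequence


def test_three_frame_translation():
    segs = three_frame_translate({"tx": "ATGAAACGT"})
    assert [s.sequence for s in segs if s.frame == 1] == ["MKR"]
    # 9 nt in frame 3 leaves two full codons
    frame3 = [s for s in segs if s.frame == 3]
    assert sum(len(s.sequence) for s in frame3) == 2
    assert all(s.strand == "+" for s in segs)


def test_subtract_known_equivalences():
    known = {collapse_il("IEPTIDEK"), collapse_il("NGGARAAA")}
    retained, report = subtract_known(
        ["LEPTIDEK", "DGGARAAA", "QQQQQQQK"], known
    )
    assert "LEPTIDEK" in report["removed_exact"]
    assert "DGGARAAA" in report["flagged_nd"]  # flagged, not removed, at build
    assert [p for p in retained] == ["DGGARAAA", "QQQQQQQK"]
    retained_nd, _ = subtract_known(["DGGARAAA"], known, remove_nd=True)
    assert retained_nd == []


def test_fraction_windows_margin_overlap():
    windows = fraction_windows("IPG3-10", [0, 1], margin=0.11)
    lo0, hi0 = windows[0]
    lo1, hi1 = windows[1]
    # abutting experimental intervals overlap by exactly 2 * margin
    assert hi0 - lo1 == pytest.approx(0.22)


def test_build_6ft_db_contents(toy_genome):
    config = PartitionConfig(strip="IPG3-10")
    fractions = range(72)
    per_fraction, unique, report = build_6ft_db(
        toy_genome.genome, toy_genome.proteins, fractions, config
    )
    truth = toy_genome.novel_peptide_truth
    recovered = {group[0].sequence for group in unique}
    assert recovered == truth

    windows = fraction_windows("IPG3-10", fractions, config.margin)
    for group in unique:
        pep = group[0]
        assert 8 <= len(pep.sequence) <= 30
        in_fracs = {
            f for f, (lo, hi) in windows.items() if lo <= pep.predicted_pi <= hi
        }
        for f in in_fracs:
            assert pep.sequence in per_fraction[f].values()
    # canonical proteome appended to every fraction database
    name = next(iter(toy_genome.proteins))
    for f in fractions:
        assert per_fraction[f][name] == toy_genome.proteins[name]


def test_no_duplicate_sequences_per_fraction(toy_genome):
    per_fraction, _unique, _report = build_6ft_db(
        toy_genome.genome, toy_genome.proteins, range(72),
        PartitionConfig(strip="IPG3-10"), append_proteome=False,
    )
    for entries in per_fraction.values():
        seqs = list(entries.values())
        assert len(seqs) == len(set(seqs))


def test_boundary_pi_enters_both_windows():
    windows = fraction_windows("IPG3-10", [0, 1], margin=0.11)
    boundary = windows[0][1] - 0.005  # inside frac0's upper margin and frac1
    assert windows[0][0] <= boundary <= windows[0][1]
    assert windows[1][0] <= boundary <= windows[1][1]


@pytest.mark.parametrize(
    "protein,variant,expected",
    [
        ("MAKDLK", ("p", 4, "D", "E"), [("ELK", 1, "D", "E")]),
    ],
)
def test_saav_substitute_and_redigest(protein, variant, expected):
    peptides, rejects = build_saav_peptides({"p": protein}, [variant])
    assert not rejects
    got = [(p.sequence, p.sub_pos, p.ref, p.alt) for p in peptides]
    assert got == expected


def test_saav_new_cleavage_site_redigested():
    # G4K creates a new tryptic site: products reflect re-digestion
    peptides, _ = build_saav_peptides({"p": "MAAGLLK"}, [("p", 4, "G", "K")])
    assert {p.sequence for p in peptides} == {"MAAK"}


def test_saav_il_flagged_indistinguishable():
    peptides, _ = build_saav_peptides({"p": "MAAILEK"}, [("p", 4, "I", "L")])
    assert peptides and all(p.indistinguishable for p in peptides)


def test_saav_ref_mismatch_rejected():
    peptides, rejects = build_saav_peptides({"p": "MAKDLK"}, [("p", 4, "E", "Q")])
    assert not peptides
    assert rejects and "ref mismatch" in rejects[0]["reason"]


def test_decoy_db_bijection_and_report():
    targets = {"a": "LVDEK", "b": "AAK", "c": "AK"}
    decoys, report = build_decoy_db(targets)
    assert len(decoys) == 3
    assert decoys["decoy_a"] == "EDVLK"
    assert set("".join(decoys.values())) == set("".join(targets.values()))
    assert "AK" in report["self_decoys"]


def test_canonical_only_genome_is_empty_after_subtraction():
    from ipaw.synthetic_fixtures import ToyGenomeSpec, make_toy_genome

    spec = ToyGenomeSpec(
        n_pseudogenes=0, n_lncrna=0, n_intergenic_orfs=0,
        n_utr5_extensions=0, n_altorfs=0,
    )
    toy = make_toy_genome(spec, seed=5)
    known = known_peptide_index(toy.proteins)
    retained, _ = subtract_known(
        segments_to_peptides(six_frame_translate(toy.genome)), known
    )
    assert retained == []
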