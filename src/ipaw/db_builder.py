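"""Search-space database construction.

Builds the discovery-stage databases: pI-restricted six-frame-translation
(6FT) peptide databases partitioned by HiRIEF fraction, three-frame
translations of transcript/ncRNA sequences, single-amino-acid-variant
(SAAV) peptide sets from variant catalogs, known-peptide subtraction under
residue equivalences, and reversed-tryptic decoy companions.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .constants import STANDARD_RESIDUES
from .peptides import Peptide, digest, generate_decoy
from .pi_model import DEFAULT_STRIPS, IPGStripCalibration, fraction_to_pi, predict_pi

__all__ = [
    "GenomicPeptide",
    "SAAVPeptide",
    "PartitionConfig",
    "TranslatedSegment",
    "six_frame_translate",
    "three_frame_translate",
    "build_6ft_db",
    "build_saav_peptides",
    "subtract_known",
    "build_decoy_db",
    "collapse_il",
    "known_peptide_index",
    "fraction_windows",
]


def collapse_il(sequence: str) -> str:
    """Isoleucine and leucine are isobaric: collapse I to L for matching."""
    return sequence.replace("I", "L")


def _nd_key(sequence: str) -> str:
    """Key under which deamidation-explainable sequences collide (N->D)."""
    return collapse_il(sequence).replace("N", "D")


@dataclass(frozen=True)
class GenomicPeptide:
    """A tryptic peptide from genomic translation with its coordinates."""

    sequence: str
    chrom: str
    strand: str  # "+" | "-"
    frame: int  # 1..6 (1-3 forward, 4-6 reverse)
    blocks: tuple  # ((start, end), ...) 0-based half-open
    predicted_pi: float | None = None

    def __post_init__(self):
        total = sum(end - start for start, end in self.blocks)
        if total != 3 * len(self.sequence):
            raise ValueError("block lengths must sum to 3x peptide length")


@dataclass(frozen=True)
class SAAVPeptide:
    """A variant peptide carrying exactly one amino-acid substitution."""

    sequence: str
    parent_protein: str
    sub_pos: int  # 1-based within the peptide
    ref: str
    alt: str
    source: str = ""
    start_in_protein: int = 1
    indistinguishable: bool = False  # I<->L substitution, isobaric

    def __post_init__(self):
        if self.sequence[self.sub_pos - 1] != self.alt:
            raise ValueError("sequence does not carry alt residue at sub_pos")


@dataclass(frozen=True)
class PartitionConfig:
    """Fraction-window partitioning parameters for pI-restricted databases.

    ``margin`` widens each experimental fraction interval on both sides to
    absorb the pI prediction error (default 0.11 pI units, the 95%
    confidence margin of the predictor).
    """

    margin: float = 0.11
    min_length: int = 8
    max_length: int = 30
    strip: str = "IPG3-10"

    def __post_init__(self):
        if self.margin < 0 or self.min_length < 1 or self.max_length < self.min_length:
            raise ValueError("invalid partition configuration")


@dataclass(frozen=True)
class TranslatedSegment:
    """A stop-free translated stretch of one reading frame.

    ``aa_coords`` maps amino acid i (0-based within the segment) to genomic
    block [start + 3i, start + 3i + 3) on "+", or counted from ``end``
    leftward on "-".
    """

    chrom: str
    strand: str
    frame: int
    sequence: str
    genomic_start: int  # genomic coordinate of the first codon's first base ("+")
    genomic_end: int  # exclusive end of the last codon ("+"); for "-" see block()

    def block(self, aa_start: int, aa_len: int) -> tuple:
        """Genomic (start, end) of residues [aa_start, aa_start+aa_len)."""
        if self.strand == "+":
            start = self.genomic_start + 3 * aa_start
            return (start, start + 3 * aa_len)
        end = self.genomic_end - 3 * aa_start
        return (end - 3 * aa_len, end)


def _frame_segments(chrom, seq, frame_index, offset, strand, length):
    """Split one reading frame at stop codons into TranslatedSegments."""
    n_codons = (len(seq) - offset) // 3
    if n_codons <= 0:
        return
    coding = seq[offset : offset + 3 * n_codons]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # partial-codon warnings are handled above
        aa = str(Seq(coding).translate())
    pos = 0
    for piece in aa.split("*"):
        if piece:
            if strand == "+":
                g_start = offset + 3 * pos
                g_end = g_start + 3 * len(piece)
            else:
                # position pos on the reverse-complement maps rightward from
                # the chromosome end
                g_end = length - offset - 3 * pos
                g_start = g_end - 3 * len(piece)
            yield TranslatedSegment(chrom, strand, frame_index, piece, g_start, g_end)
        pos += len(piece) + 1


def six_frame_translate(genome: dict[str, str]) -> list[TranslatedSegment]:
    """Translate every chromosome in all six reading frames.

    Frames 1-3 are the forward strand at offsets 0-2; frames 4-6 the
    reverse complement at offsets 0-2. Segments are split at stop codons
    (the stop itself is not translated); codons containing ambiguous bases
    become X. Empty sequences are skipped with a warning.
    """
    segments = []
    for chrom, seq in genome.items():
        seq = seq.upper()
        if not seq:
            warnings.warn(f"skipping empty sequence {chrom!r}")
            continue
        rc = str(Seq(seq).reverse_complement())
        for offset in range(3):
            segments.extend(
                _frame_segments(chrom, seq, offset + 1, offset, "+", len(seq))
            )
            segments.extend(
                _frame_segments(chrom, rc, offset + 4, offset, "-", len(seq))
            )
    return segments


def three_frame_translate(transcripts: dict[str, str]) -> list[TranslatedSegment]:
    """Translate sense-strand transcripts in three forward frames.

    Coordinates are transcript-relative (chrom = transcript id, strand "+");
    genome mapping is a separate splice-aware step.
    """
    segments = []
    for tx_id, seq in transcripts.items():
        seq = seq.upper()
        if not seq:
            warnings.warn(f"skipping empty transcript {tx_id!r}")
            continue
        for offset in range(3):
            segments.extend(
                _frame_segments(tx_id, seq, offset + 1, offset, "+", len(seq))
            )
    return segments


def known_peptide_index(proteins: dict[str, str]) -> set[str]:
    """I/L-collapsed set of all fully tryptic peptides of a proteome."""
    index = set()
    for seq in proteins.values():
        for pep in digest(seq):
            index.add(collapse_il(pep.sequence))
    return index


def segments_to_peptides(
    segments: list[TranslatedSegment],
    min_length: int = 8,
    max_length: int = 30,
) -> list[GenomicPeptide]:
    """Digest translated segments into length-filtered genomic peptides.

    Peptides containing non-standard residues (X from ambiguous bases) are
    dropped: their mass and pI are undefined.
    """
    peptides = []
    for seg in segments:
        offset = 0
        for pep in digest(seg.sequence):
            length = len(pep.sequence)
            if (
                min_length <= length <= max_length
                and not (set(pep.sequence) - STANDARD_RESIDUES)
            ):
                peptides.append(
                    GenomicPeptide(
                        pep.sequence,
                        seg.chrom,
                        seg.strand,
                        seg.frame,
                        (seg.block(offset, length),),
                    )
                )
            offset += length
    return peptides


def subtract_known(
    peptides,
    known_index: set[str],
    *,
    flag_nd: bool = True,
    remove_nd: bool = False,
):
    """Remove peptides matching the known proteome under I=L.

    Returns (retained, report). ``report["removed_exact"]`` lists sequences
    equal to a known tryptic peptide with I=L; deamidation-explainable
    sequences (equal under an additional N->D mapping) are listed in
    ``report["flagged_nd"]`` and retained unless ``remove_nd`` — the
    FDR stage applies the discard.
    """
    nd_index = {_nd_key(k) for k in known_index} if (flag_nd or remove_nd) else set()
    retained, removed, flagged = [], [], []
    for pep in peptides:
        seq = pep.sequence if hasattr(pep, "sequence") else pep
        key = collapse_il(seq)
        if key in known_index:
            removed.append(seq)
            continue
        nd_hit = bool(nd_index) and _nd_key(seq) in nd_index
        if nd_hit and remove_nd:
            removed.append(seq)
            continue
        if nd_hit:
            flagged.append(seq)
        retained.append(pep)
    return retained, {"removed_exact": removed, "flagged_nd": flagged}


def fraction_windows(
    strip: IPGStripCalibration | str,
    fractions,
    margin: float = 0.11,
) -> dict[int, tuple]:
    """Experimental pI window [lo - margin, hi + margin] per fraction.

    Fraction f spans the strip from fraction number f to f+1; on strips
    running alkaline-to-acidic the bounds are swapped so lo < hi.
    """
    windows = {}
    for f in fractions:
        a = fraction_to_pi(strip, f)
        b = fraction_to_pi(strip, f + 1)
        lo, hi = min(a, b), max(a, b)
        windows[f] = (lo - margin, hi + margin)
    return windows


def build_6ft_db(
    genome: dict[str, str],
    known_proteins: dict[str, str],
    fractions,
    config: PartitionConfig | None = None,
    *,
    pk_table=None,
    mod_config=None,
    append_proteome: bool = True,
):
    """pI-restricted six-frame peptide databases, one per HiRIEF fraction.

    Pipeline: six-frame translate -> tryptic digest -> drop X -> subtract
    known (I=L) -> deduplicate retaining all genomic positions -> length
    filter -> predict pI -> assign each peptide to every fraction whose
    margin-widened window contains it (window edges inclusive, so a peptide
    on a boundary enters both neighbors). The canonical proteome is appended
    to every fraction database as whole-protein entries for the downstream
    search engine to digest.

    Returns (per_fraction FASTA dicts, unique GenomicPeptide groups, report).
    """
    config = config or PartitionConfig()
    known = known_peptide_index(known_proteins)
    raw = segments_to_peptides(
        six_frame_translate(genome), config.min_length, config.max_length
    )
    retained, report = subtract_known(raw, known)

    # dedupe by sequence, recording every genomic locus
    groups: dict[str, list[GenomicPeptide]] = {}
    for pep in retained:
        groups.setdefault(pep.sequence, []).append(pep)

    windows = fraction_windows(config.strip, fractions, config.margin)
    per_fraction: dict[int, dict[str, str]] = {f: {} for f in fractions}
    unique = []
    for seq in sorted(groups):
        loci = sorted(
            groups[seq], key=lambda p: (p.chrom, p.blocks[0][0], p.strand, p.frame)
        )
        pi = predict_pi(seq, pk_table, mod_config)
        unique.append([
            GenomicPeptide(p.sequence, p.chrom, p.strand, p.frame, p.blocks, pi)
            for p in loci
        ])
        header = ";".join(
            f"{p.chrom}|{p.blocks[0][0]}|{p.blocks[-1][1]}|{p.strand}|{p.frame}"
            for p in loci
        )
        for f, (lo, hi) in windows.items():
            if lo <= pi <= hi:
                per_fraction[f][header] = seq

    if append_proteome:
        for f in fractions:
            for name, seq in known_proteins.items():
                per_fraction[f][name] = seq

    report["n_unique"] = len(unique)
    return per_fraction, unique, report


def build_saav_peptides(
    proteins: dict[str, str],
    variants,
) -> tuple[list[SAAVPeptide], list[dict]]:
    """SAAV peptides from a variant table by mutate-then-redigest.

    ``variants`` rows are (protein_id, position, ref, alt, source) with
    1-based protein positions. The mutated protein is re-digested so
    substitutions creating or destroying cleavage sites yield the correct
    tryptic products; only peptides containing the substituted position are
    kept. Records whose reference residue does not match are rejected into
    the returned report.
    """
    peptides, rejects = [], []
    for protein_id, pos, ref, alt, *rest in variants:
        source = rest[0] if rest else ""
        protein = proteins.get(protein_id)
        pos = int(pos)
        if protein is None:
            rejects.append({"protein": protein_id, "pos": pos, "reason": "unknown protein"})
            continue
        if not 1 <= pos <= len(protein):
            rejects.append({"protein": protein_id, "pos": pos, "reason": "position out of range"})
            continue
        if protein[pos - 1] != ref:
            rejects.append(
                {"protein": protein_id, "pos": pos,
                 "reason": f"ref mismatch: protein has {protein[pos - 1]}"}
            )
            continue
        mutated = protein[: pos - 1] + alt + protein[pos:]
        for pep in digest(mutated):
            start = pep.start_in_protein
            if start <= pos < start + len(pep.sequence):
                peptides.append(
                    SAAVPeptide(
                        pep.sequence,
                        protein_id,
                        pos - start + 1,
                        ref,
                        alt,
                        source,
                        start_in_protein=start,
                        indistinguishable=collapse_il(ref) == collapse_il(alt),
                    )
                )
    return peptides, rejects


def build_decoy_db(targets: dict[str, str]) -> tuple[dict[str, str], dict]:
    """Reversed-tryptic decoy FASTA for a target peptide FASTA.

    One decoy per target, header prefixed ``decoy_``. The report flags
    self-mapping decoys (palindromic prefixes) and decoys colliding with a
    target sequence.
    """
    target_seqs = set(targets.values())
    decoys = {}
    report = {"self_decoys": [], "target_collisions": []}
    for header, seq in targets.items():
        decoy_seq = generate_decoy(seq).sequence
        decoys[f"decoy_{header}"] = decoy_seq
        if decoy_seq == seq:
            report["self_decoys"].append(seq)
        elif decoy_seq in target_seqs:
            report["target_collisions"].append(decoy_seq)
    return decoys, report
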