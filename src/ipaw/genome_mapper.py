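"""Peptide-to-genome mapping, locus grouping and event classification.

Transcript-relative peptides are projected through exon structures to
spliced genomic blocks; peptides within 10 kb chain into loci; each locus
is classified into one unannotated-coding event category (pseudogene,
5'UTR, intronic, AltORF, ncRNA, exon extension, intergenic, 3'UTR) under a
fixed precedence; and the surrounding open reading frame is scanned for
upstream canonical and near-cognate start codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

__all__ = [
    "TranscriptModel",
    "PeptideLocus",
    "EventCall",
    "map_to_genome",
    "detect_multimapping",
    "group_loci",
    "classify_event",
    "orf_context",
    "NEAR_COGNATE_CODONS",
    "EVENT_PRECEDENCE",
]

# codons one base away from ATG that support near-cognate initiation
NEAR_COGNATE_CODONS = (
    "CTG", "GTG", "TTG", "ACG", "AAG", "AGG", "ATA", "ATC", "ATT",
)

EVENT_PRECEDENCE = (
    "pseudogene",
    "ncRNA",
    "AltORF",
    "5'UTR",
    "3'UTR",
    "exon extension",
    "intronic",
    "intergenic",
)

PSEUDOGENE_BIOTYPES = {
    "pseudogene", "processed_pseudogene", "unprocessed_pseudogene",
    "transcribed_pseudogene", "polymorphic_pseudogene",
}
NCRNA_BIOTYPES = {"lncRNA", "lincRNA", "ncRNA", "antisense", "miRNA", "snoRNA"}


@dataclass(frozen=True)
class TranscriptModel:
    """A strand-aware transcript: ordered exons and optional CDS span."""

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple  # ((start, end), ...) sorted by genomic start, 0-based half-open
    cds: tuple | None = None  # genomic (start, end) span of the CDS
    biotype: str = "protein_coding"

    def __post_init__(self):
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError("exons must be non-overlapping and sorted")
        if self.cds is not None:
            lo, hi = self.cds
            if lo < self.exons[0][0] or hi > self.exons[-1][1]:
                raise ValueError("CDS outside exon span")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def genomic_positions(self) -> list[int]:
        """Genomic coordinate of each transcript base, 5' to 3'."""
        positions = [p for s, e in self.exons for p in range(s, e)]
        return positions[::-1] if self.strand == "-" else positions


@dataclass(frozen=True)
class PeptideLocus:
    """A peptide placed on the genome as ordered spliced blocks."""

    peptide: str
    chrom: str
    strand: str
    blocks: tuple  # sorted by genomic start
    frame: int | None = None
    locus_id: str | None = None

    def __post_init__(self):
        total = sum(e - s for s, e in self.blocks)
        if total != 3 * len(self.peptide):
            raise ValueError("block lengths must sum to 3x peptide length")

    @property
    def span(self) -> tuple:
        return (self.blocks[0][0], self.blocks[-1][1])


@dataclass(frozen=True)
class EventCall:
    category: str
    supporting: tuple = ()


def _runs(positions) -> tuple:
    """Collapse a sorted position list into half-open blocks."""
    blocks = []
    start = prev = positions[0]
    for p in positions[1:]:
        if p != prev + 1:
            blocks.append((start, prev + 1))
            start = p
        prev = p
    blocks.append((start, prev + 1))
    return tuple(blocks)


def map_to_genome(
    peptide: str,
    tx_start_nt: int,
    transcript: TranscriptModel,
    frame: int | None = None,
) -> PeptideLocus:
    """Project a transcript-relative peptide to spliced genomic blocks.

    ``tx_start_nt`` is the 0-based transcript coordinate of the codon
    encoding the first residue. Minus-strand transcripts read right to
    left, so blocks count from the exon ends. The round trip — extract the
    blocks, reverse-complement on minus, translate — reproduces the
    peptide.
    """
    n_nt = 3 * len(peptide)
    if tx_start_nt < 0 or tx_start_nt + n_nt > transcript.length:
        raise ValueError("peptide span exceeds transcript length")
    genomic = transcript.genomic_positions()[tx_start_nt : tx_start_nt + n_nt]
    blocks = _runs(sorted(genomic))
    return PeptideLocus(
        peptide, transcript.chrom, transcript.strand, blocks, frame=frame
    )


def extract_and_translate(locus: PeptideLocus, genome: dict[str, str]) -> str:
    """Translate the genomic sequence under a locus (round-trip check)."""
    seq = "".join(genome[locus.chrom][s:e] for s, e in locus.blocks)
    if locus.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return str(Seq(seq).translate())


def detect_multimapping(peptide: str, genomic_peptide_index: dict) -> int:
    """Count genomic loci carrying a peptide in any frame/strand.

    ``genomic_peptide_index`` maps sequence -> list of loci from the
    six-frame index. Count 0 means the peptide only exists across a splice
    junction; count > 1 flags an ambiguous, deprioritized peptide.
    """
    return len(genomic_peptide_index.get(peptide, ()))


def group_loci(loci, gap: int = 10000) -> dict:
    """Single-linkage grouping of peptides within ``gap`` bp on a chromosome.

    Peptides whose spans are separated by at most ``gap`` chain into one
    locus; group ids are ``{chrom}:{leftmost start}`` so the assignment is
    deterministic and invariant to input order.
    """
    loci = list(loci)
    by_chrom: dict[str, list] = {}
    for idx, locus in enumerate(loci):
        by_chrom.setdefault(locus.chrom, []).append(idx)

    assignment = {}
    for chrom, indices in by_chrom.items():
        indices.sort(key=lambda i: loci[i].span)
        cluster: list[int] = []
        cluster_end = None
        for i in indices:
            start, end = loci[i].span
            if cluster and start - cluster_end > gap:
                leftmost = min(loci[j].span[0] for j in cluster)
                for j in cluster:
                    assignment[j] = f"{chrom}:{leftmost}"
                cluster = []
                cluster_end = None
            cluster.append(i)
            cluster_end = end if cluster_end is None else max(cluster_end, end)
        if cluster:
            leftmost = min(loci[j].span[0] for j in cluster)
            for j in cluster:
                assignment[j] = f"{chrom}:{leftmost}"
    return {i: assignment[i] for i in range(len(loci))}


def _overlap(a: tuple, b: tuple) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def classify_event(locus: PeptideLocus, annotation) -> EventCall:
    """One event category per peptide locus under a fixed precedence.

    ``annotation`` is an iterable of TranscriptModel. Precedence:
    pseudogene exon overlap > ncRNA exon overlap > out-of-frame CDS overlap
    (AltORF) > 5'UTR > 3'UTR > exon-boundary extension > intronic >
    intergenic. An empty annotation yields intergenic.
    """
    span = locus.span
    hits = {cat: [] for cat in EVENT_PRECEDENCE}
    for tx in annotation:
        if tx.chrom != locus.chrom:
            continue
        exon_overlap = any(
            _overlap(span, exon) for exon in tx.exons
        )
        tx_span = (tx.exons[0][0], tx.exons[-1][1])
        span_overlap = _overlap(span, tx_span) > 0
        if not span_overlap:
            continue
        if tx.biotype in PSEUDOGENE_BIOTYPES:
            if exon_overlap:
                hits["pseudogene"].append(tx.transcript_id)
            continue
        if tx.biotype in NCRNA_BIOTYPES:
            if exon_overlap:
                hits["ncRNA"].append(tx.transcript_id)
            continue
        # protein-coding context
        if tx.cds is not None and _overlap(span, tx.cds) > 0 and exon_overlap:
            cds_frame = tx.cds[0] % 3 if tx.strand == "+" else tx.cds[1] % 3
            pep_frame = (
                span[0] % 3 if locus.strand == "+" else span[1] % 3
            )
            if locus.strand != tx.strand or cds_frame != pep_frame:
                hits["AltORF"].append(tx.transcript_id)
            else:
                hits["exon extension"].append(tx.transcript_id)
            continue
        if tx.cds is not None and exon_overlap:
            # exonic but outside the CDS: UTR side by strand
            if (span[1] <= tx.cds[0]) == (tx.strand == "+"):
                hits["5'UTR"].append(tx.transcript_id)
            else:
                hits["3'UTR"].append(tx.transcript_id)
            continue
        if exon_overlap:
            hits["exon extension"].append(tx.transcript_id)
            continue
        hits["intronic"].append(tx.transcript_id)

    for category in EVENT_PRECEDENCE:
        if hits[category]:
            return EventCall(category, tuple(sorted(set(hits[category]))))
    return EventCall("intergenic")


@dataclass
class OrfContext:
    """Upstream in-frame start-codon candidates and the downstream stop."""

    candidates: tuple  # ((genomic position of codon start, codon, context), ...)
    upstream_stop: int | None
    downstream_stop: int | None
    truncated: bool = False


def orf_context(
    locus: PeptideLocus,
    genome: dict[str, str],
    context_pad: int = 6,
) -> OrfContext:
    """Scan the reading frame around a contiguous locus for start codons.

    Walks in-frame upstream (5' of the peptide on its coding strand) to the
    nearest stop codon, collecting ATG and near-cognate codons with their
    surrounding nucleotide context, and finds the first in-frame downstream
    stop. Reaching the contig edge sets the truncated flag.
    """
    chrom_seq = genome[locus.chrom]
    if locus.strand == "-":
        seq = str(Seq(chrom_seq).reverse_complement())
        # coding-strand coordinate of the first peptide base
        start = len(chrom_seq) - locus.span[1]
    else:
        seq = chrom_seq
        start = locus.span[0]

    def genomic_pos(coding_pos: int) -> int:
        if locus.strand == "+":
            return coding_pos
        return len(chrom_seq) - coding_pos - 3

    stops = {"TAA", "TAG", "TGA"}
    candidates = []
    upstream_stop = None
    truncated = False
    pos = start - 3
    while pos >= 0:
        codon = seq[pos : pos + 3]
        if codon in stops:
            upstream_stop = genomic_pos(pos)
            break
        if codon == "ATG" or codon in NEAR_COGNATE_CODONS:
            context = seq[max(0, pos - context_pad) : pos + 3 + context_pad]
            candidates.append((genomic_pos(pos), codon, context))
        pos -= 3
    else:
        truncated = True

    downstream_stop = None
    pos = start + 3 * len(locus.peptide)
    while pos + 3 <= len(seq):
        codon = seq[pos : pos + 3]
        if codon in stops:
            downstream_stop = genomic_pos(pos)
            break
        pos += 3
    else:
        truncated = True

    # nearest-first: candidates were collected walking away from the peptide
    return OrfContext(tuple(candidates), upstream_stop, downstream_stop, truncated)
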