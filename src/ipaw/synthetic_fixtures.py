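"""Seeded generators for every input the workflow consumes.

The toy genome plants canonical genes, diverged pseudogene copies, an
lncRNA with an embedded open reading frame, an intergenic ORF, an
N-terminal extension reachable from a near-cognate start, and a
dual-coding AltORF — the unannotated-coding event classes the pipeline is
meant to rediscover — and retains a truth record for each.

Two design points make the fixtures exact rather than statistical. First,
intergenic spacers are CTAG repeats: CTAG is its own reverse complement
as a repeat unit and places a stop codon in every reading frame on both
strands within 12 nt, so spacer DNA can never yield a credible tryptic
peptide. Second, coding sequences are "quiet-encoded": synonymous codons
are re-sampled until the five non-coding frames of each planted element
(checked with flanking spacer context) contain no tryptic peptide in the
searched length range. Novel peptides in the six-frame space therefore
come from planted elements only, and each element's expected peptides are
computed from its designed protein sequence, independent of the database
builder.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .constants import STANDARD_RESIDUES
from .db_builder import collapse_il
from .genome_mapper import TranscriptModel
from .io import Spectrum, write_fasta
from .peptides import ModConfig, Peptide, digest, fragment_ions
from .spectrum_ai import PSM, flanking_requirements

__all__ = [
    "ToyGenomeSpec",
    "ToyGenome",
    "SpectrumBenchSpec",
    "make_toy_genome",
    "make_spectra",
    "make_score_mixture",
]

SPACER_UNIT = "CTAG"
STOPS = {"TAA", "TAG", "TGA"}

CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "N": ["AAT", "AAC"],
    "D": ["GAT", "GAC"],
    "C": ["TGT", "TGC"],
    "Q": ["CAA", "CAG"],
    "E": ["GAA", "GAG"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "K": ["AAA", "AAG"],
    "M": ["ATG"],
    "F": ["TTT", "TTC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
}

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
# residue frequencies giving realistic tryptic peptide lengths
AA_WEIGHTS = np.array([7, 2, 5, 6, 4, 7, 2, 5, 6, 9, 2, 4, 5, 4, 6, 7, 5, 6, 1, 3], float)
AA_WEIGHTS /= AA_WEIGHTS.sum()


@dataclass(frozen=True)
class ToyGenomeSpec:
    """Composition of the synthetic genome.

    Element counts are per genome; protein lengths are sampled uniformly
    from ``protein_length``. ``pseudogene_divergence`` is the per-residue
    point-substitution rate applied to the parent protein when planting a
    pseudogene copy (no indels, so some unique tryptic peptides are
    guaranteed).
    """

    n_genes: int = 4
    n_pseudogenes: int = 2
    n_lncrna: int = 1
    n_intergenic_orfs: int = 1
    n_utr5_extensions: int = 1
    n_altorfs: int = 1
    pseudogene_divergence: float = 0.05
    protein_length: tuple = (60, 110)
    spacer_length: int = 600
    min_peptide_len: int = 8
    max_peptide_len: int = 30
    chrom_name: str = "chr1"


@dataclass
class TruthRecord:
    element_id: str
    category: str  # classify_event vocabulary, or "canonical"
    chrom: str
    start: int
    end: int
    strand: str
    novel_peptides: tuple = ()


@dataclass
class ToyGenome:
    genome: dict
    proteins: dict  # known proteome
    annotation: list  # TranscriptModel
    truth: list  # TruthRecord

    @property
    def novel_peptide_truth(self) -> set:
        return {p for rec in self.truth for p in rec.novel_peptides}

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fasta")
        write_fasta(self.proteins, outdir / "proteins.fasta")
        with open(outdir / "annotation.gtf", "w") as fh:
            for tx in self.annotation:
                for start, end in tx.exons:
                    fh.write(
                        f"{tx.chrom}\tipaw_sim\texon\t{start + 1}\t{end}\t.\t"
                        f"{tx.strand}\t.\tgene_id \"{tx.transcript_id}\"; "
                        f"transcript_id \"{tx.transcript_id}\"; "
                        f"gene_biotype \"{tx.biotype}\";\n"
                    )
                if tx.cds is not None:
                    fh.write(
                        f"{tx.chrom}\tipaw_sim\tCDS\t{tx.cds[0] + 1}\t{tx.cds[1]}\t.\t"
                        f"{tx.strand}\t0\tgene_id \"{tx.transcript_id}\"; "
                        f"transcript_id \"{tx.transcript_id}\";\n"
                    )
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("element_id\tcategory\tchrom\tstart\tend\tstrand\tnovel_peptides\n")
            for rec in self.truth:
                fh.write(
                    f"{rec.element_id}\t{rec.category}\t{rec.chrom}\t{rec.start}\t"
                    f"{rec.end}\t{rec.strand}\t{','.join(rec.novel_peptides)}\n"
                )


def _random_protein(rng, length: int) -> str:
    aas = rng.choice(list(AA_ALPHABET), size=length, p=AA_WEIGHTS)
    protein = "".join(aas)
    # a tryptic C-terminus keeps element boundaries clean
    return protein[:-1] + rng.choice(["K", "R"])


def _spacer(length: int) -> str:
    return (SPACER_UNIT * (length // len(SPACER_UNIT) + 1))[:length]


def _tryptic_in_range(aa_seq: str, lo: int, hi: int) -> list[str]:
    """Length-filtered standard-residue tryptic peptides of a translation."""
    out = []
    for run in aa_seq.split("*"):
        if not run:
            continue
        for pep in digest(run):
            if lo <= len(pep.sequence) <= hi and not (
                set(pep.sequence) - STANDARD_RESIDUES
            ):
                out.append(pep.sequence)
    return out


def _offending_windows(dna: str, allowed: set, lo: int, hi: int):
    """(frame label, nt start, nt end) of unexpected tryptic peptides.

    Scans all six frames of ``dna``; peptides whose I/L-collapsed sequence
    is in ``allowed`` are expected and ignored. nt coordinates refer to
    the forward strand of ``dna``.
    """
    windows = []
    rc = str(Seq(dna).reverse_complement())
    for strand, seq in (("+", dna), ("-", rc)):
        for offset in range(3):
            n_codons = (len(seq) - offset) // 3
            if n_codons <= 0:
                continue
            aa = str(Seq(seq[offset : offset + 3 * n_codons]).translate())
            pos = 0
            for run in aa.split("*"):
                if run:
                    aa_off = 0
                    for pep in digest(run):
                        ok = (
                            not (lo <= len(pep.sequence) <= hi)
                            or (set(pep.sequence) - STANDARD_RESIDUES)
                            or collapse_il(pep.sequence) in allowed
                        )
                        if not ok:
                            a = offset + 3 * (pos + aa_off)
                            b = a + 3 * len(pep.sequence)
                            if strand == "-":
                                a, b = len(dna) - b, len(dna) - a
                            windows.append((f"{strand}{offset}", a, b))
                        aa_off += len(pep.sequence)
                pos += len(run) + 1
    return windows


# forward 3-mers whose reverse complement is a stop codon
REV_STOPS = {"TTA", "CTA", "TCA"}


def _greedy_codons(protein: str, rng, fixed: dict | None = None) -> list:
    """Synonymous codons chosen to seed stops into the five other frames.

    Walks the protein left to right tracking, for each shifted forward
    frame and each reverse-frame phase, how long ago the last stop codon
    appeared; each codon is chosen (among synonymous options, with seeded
    random tie-breaking) to cap the neediest frames. This keeps stop-free
    runs in non-coding frames far below the minimum peptide length most of
    the time; a verification/repair pass removes the stragglers.
    """
    fixed = fixed or {}
    # trackers: +1/+2 forward shifted frames, reverse phases 0/1/2
    frames = ["f1", "f2", "r0", "r1", "r2"]
    last = {f: 0 for f in frames}
    codons: list[str] = []
    tail = "AG"  # last two bases of the upstream spacer unit CTAG
    for k, aa in enumerate(protein):
        options = [fixed[k]] if k in fixed else CODONS[aa]
        scored = []
        for codon in options:
            t1 = tail[-2] + tail[-1] + codon[0]
            t2 = tail[-1] + codon[0] + codon[1]
            hits = []
            if t1 in STOPS:
                hits.append("f1")
            if t2 in STOPS:
                hits.append("f2")
            if t1 in REV_STOPS:
                hits.append("r1")
            if t2 in REV_STOPS:
                hits.append("r2")
            if codon in REV_STOPS:
                hits.append("r0")
            score = sum(k - last[f] for f in hits)
            scored.append((score, rng.random(), codon, hits))
        _score, _tie, codon, hits = max(scored)
        codons.append(codon)
        for f in hits:
            last[f] = k
        tail = codon[-2:]
    return codons


def _quiet_encode(
    protein: str,
    allowed: set,
    rng,
    lo: int,
    hi: int,
    prefix: str = "",
    suffix: str = "TAA",
    fixed: dict | None = None,
    pad: int = 16,
    max_iter: int = 30,
) -> str:
    """Encode a protein suppressing tryptic peptides in the other frames.

    The check runs on ``spacer + prefix + CDS + suffix + spacer`` — the
    exact genomic context the element will occupy. Codons come from the
    stop-seeding greedy chooser; a short local search then swaps synonymous
    codons to shrink residual offending windows (tryptic peptides whose
    collapsed sequence is not in ``allowed``). Some windows admit no
    synonymous fix, so the result is best-effort: the genome assembler
    absorbs whatever survives into the synthetic background proteome.
    ``fixed`` pins codon indices (a forced near-cognate start, a
    dual-coded block) that must never be resampled. Returns the CDS only.
    """
    fixed = fixed or {}
    codons = _greedy_codons(protein, rng, fixed)
    left = _spacer(pad) + prefix
    right = suffix + _spacer(pad)

    def offenses():
        dna = left + "".join(codons) + right
        return _offending_windows(dna, allowed, lo, hi)

    def cost(windows):
        # total offending footprint: rewards both removing and splitting
        # long runs (a split sheds the stop codon's three bases)
        return sum(b - a for _l, a, b in windows)

    bad = offenses()
    for _ in range(max_iter):
        if not bad:
            return "".join(codons)
        # local search on one offending window: keep the first single-codon
        # synonymous substitution that lowers the offending footprint
        _label, a, b = bad[int(rng.integers(0, len(bad)))]
        c0 = max(0, (a - len(left)) // 3 - 1)
        c1 = min(len(codons), (b - len(left) + 2) // 3 + 2)
        candidates = [
            (idx, opt)
            for idx in range(c0, c1)
            if idx not in fixed
            for opt in CODONS[protein[idx]]
            if opt != codons[idx]
        ]
        if not candidates:
            return "".join(codons)  # fixed block; leave to the sweeper
        order = rng.permutation(len(candidates))
        improved = False
        sideways = None
        for j in order:
            idx, opt = candidates[int(j)]
            old = codons[idx]
            codons[idx] = opt
            new_bad = offenses()
            if cost(new_bad) < cost(bad):
                bad = new_bad
                improved = True
                break
            if cost(new_bad) == cost(bad) and sideways is None:
                sideways = (idx, opt, new_bad)
            codons[idx] = old
        if not improved:
            if sideways is not None:
                idx, opt, bad = sideways
                codons[idx] = opt
            else:
                idx, opt = candidates[int(order[0])]
                codons[idx] = opt
                bad = offenses()
    return "".join(codons)  # residual windows go to the background sweep


def _expected_novel(aa_seq: str, known: set, lo: int, hi: int) -> tuple:
    """Tryptic peptides of a designed translation that are not known."""
    return tuple(
        sorted(
            {
                p
                for p in _tryptic_in_range(aa_seq, lo, hi)
                if collapse_il(p) not in known
            }
        )
    )


def _dual_code(alt_peptides: str, rng, max_iter: int = 200) -> tuple[str, str]:
    """DNA whose +1 frame spells ``alt_peptides`` while frame 0 stays open.

    Returns (dna, frame0 translation). The returned DNA length is a
    multiple of 3 (one leading base, the +1-frame codons, two trailing
    bases) and contains no frame-0 stop codon, so it can sit inside a
    canonical CDS while its shifted frame encodes a novel peptide.
    """
    for _ in range(max_iter):
        lead = "ACGT"[rng.integers(0, 4)]
        body = "".join(
            CODONS[aa][rng.integers(0, len(CODONS[aa]))] for aa in alt_peptides
        )
        tail = "ACGT"[rng.integers(0, 4)] + "ACGT"[rng.integers(0, 4)]
        dna = lead + body + tail
        frame0 = [dna[i : i + 3] for i in range(0, len(dna), 3)]
        if not any(c in STOPS for c in frame0):
            aa0 = str(Seq(dna).translate())
            if "*" not in aa0:
                return dna, aa0
    raise RuntimeError("dual coding did not converge")


def make_toy_genome(spec: ToyGenomeSpec | None = None, seed: int = 0) -> ToyGenome:
    """Build the synthetic genome, proteome, annotation and truth records.

    Deterministic for a given (spec, seed): the same call yields
    byte-identical FASTA output.
    """
    spec = spec or ToyGenomeSpec()
    rng = np.random.default_rng(seed)
    lo, hi = spec.min_peptide_len, spec.max_peptide_len

    pieces = [_spacer(spec.spacer_length)]
    cursor = spec.spacer_length
    proteins: dict[str, str] = {}
    annotation: list[TranscriptModel] = []
    truth: list[TruthRecord] = []
    chrom = spec.chrom_name

    def known_set():
        return {
            collapse_il(p.sequence)
            for seq in proteins.values()
            for p in digest(seq)
        }

    def plant(dna: str, strand: str) -> tuple[int, int]:
        nonlocal cursor
        if strand == "-":
            dna = str(Seq(dna).reverse_complement())
        start = cursor
        pieces.append(dna)
        cursor += len(dna)
        pieces.append(_spacer(spec.spacer_length))
        cursor += spec.spacer_length
        return start, start + len(dna)

    def protein_len():
        return int(rng.integers(spec.protein_length[0], spec.protein_length[1] + 1))

    # --- canonical genes (define the known proteome first) ---
    parents = []
    for g in range(spec.n_genes):
        protein = _random_protein(rng, protein_len())
        parents.append(protein)
        proteins[f"prot{g}"] = protein
    for g, protein in enumerate(parents):
        allowed = {collapse_il(p.sequence) for p in digest(protein)}
        cds = _quiet_encode(protein, allowed, rng, lo, hi)
        strand = "+" if g % 2 == 0 else "-"
        dna = cds + "TAA"
        start, end = plant(dna, strand)
        cds_span = (start, end - 3) if strand == "+" else (start + 3, end)
        annotation.append(
            TranscriptModel(f"gene{g}", chrom, strand, ((start, end),), cds=cds_span)
        )
        truth.append(TruthRecord(f"gene{g}", "canonical", chrom, start, end, strand))

    known = known_set()

    # --- pseudogene copies: parent protein with point substitutions ---
    for k in range(spec.n_pseudogenes):
        parent = parents[k % len(parents)]
        n_sub = max(1, int(round(spec.pseudogene_divergence * len(parent))))
        # resample mutations until the copy has a recoverable unique peptide
        for _ in range(50):
            mutated = list(parent)
            positions = rng.choice(len(parent) - 1, size=n_sub, replace=False)
            for pos in positions:
                choices = [a for a in AA_ALPHABET if a != parent[pos]]
                mutated[pos] = choices[rng.integers(0, len(choices))]
            mutated = "".join(mutated)
            expected = _expected_novel(mutated, known, lo, hi)
            if expected:
                break
        allowed = known | {collapse_il(p) for p in expected}
        cds = _quiet_encode(mutated, allowed, rng, lo, hi)
        strand = "+" if k % 2 == 0 else "-"
        start, end = plant(cds + "TAA", strand)
        annotation.append(
            TranscriptModel(
                f"pseudo{k}", chrom, strand, ((start, end),),
                biotype="processed_pseudogene",
            )
        )
        truth.append(
            TruthRecord(f"pseudo{k}", "pseudogene", chrom, start, end, strand, expected)
        )

    # --- lncRNA with embedded ORF / intergenic ORF ---
    def plant_orf(element_id, category, biotype, annotate):
        # resample until the ORF yields at least one in-range novel peptide
        for _ in range(50):
            protein = _random_protein(rng, protein_len())
            expected = _expected_novel(protein, known, lo, hi)
            if expected:
                break
        allowed = known | {collapse_il(p) for p in expected}
        cds = _quiet_encode(protein, allowed, rng, lo, hi, prefix="TAA")
        dna = "TAA" + cds + "TAA"
        start, end = plant(dna, "+")
        if annotate:
            annotation.append(
                TranscriptModel(element_id, chrom, "+", ((start, end),), biotype=biotype)
            )
        truth.append(
            TruthRecord(element_id, category, chrom, start, end, "+", expected)
        )

    for j in range(spec.n_lncrna):
        plant_orf(f"lnc{j}", "ncRNA", "lncRNA", annotate=True)
    for j in range(spec.n_intergenic_orfs):
        plant_orf(f"orf{j}", "intergenic", "", annotate=False)

    # --- N-terminal extension: near-cognate CTG start, in-frame 5'UTR ---
    for j in range(spec.n_utr5_extensions):
        # "LK" leader, then a K/R-free stretch: the extension digests into a
        # short leader plus one full-length novel peptide downstream of the
        # near-cognate CTG start, so the start stays visible upstream of it
        ext = (
            "LK"
            + "".join(rng.choice(list("ACDEFGHLMNQSTVWY"), size=max(lo + 3, 14)))
            + "R"
        )
        body = _random_protein(rng, protein_len())
        proteins[f"ext_parent{j}"] = body
        known = known_set()
        full = ext + body  # CTG initiates the leading leucine
        expected = _expected_novel(ext, known, lo, hi)
        allowed = known | {collapse_il(p) for p in expected}
        cds = _quiet_encode(
            full, allowed, rng, lo, hi, prefix="TAA", fixed={0: "CTG"}
        )
        dna = "TAA" + cds + "TAA"
        start, end = plant(dna, "+")
        cds_start = start + 3 + 3 * len(ext)
        annotation.append(
            TranscriptModel(
                f"extgene{j}", chrom, "+", ((start, end),),
                cds=(cds_start, end - 3),
            )
        )
        truth.append(
            TruthRecord(
                f"ext{j}", "5'UTR", chrom, start + 3, cds_start, "+", expected
            )
        )

    # --- AltORF: novel peptide dual-coded in the +1 frame of a new gene ---
    for j in range(spec.n_altorfs):
        body = "".join(
            rng.choice(list("ACDEFGHLMNQSTVWY"), size=max(lo + 2, 12))
        )
        alt = "K" + body + "R"
        # trailing A guarantees cleavage after the final R whatever follows
        overlay, frame0_aa = _dual_code(alt + "A", rng)
        flank_n = _random_protein(rng, 30)
        flank_c = _random_protein(rng, 30)
        host = flank_n + frame0_aa + flank_c
        trial_known = known | {collapse_il(p.sequence) for p in digest(host)}
        expected = _expected_novel(alt, trial_known, lo, hi)
        allowed = trial_known | {collapse_il(p) for p in expected}
        overlay_codons = {
            len(flank_n) + k: overlay[3 * k : 3 * k + 3]
            for k in range(len(frame0_aa))
        }
        cds = _quiet_encode(host, allowed, rng, lo, hi, fixed=overlay_codons)
        proteins[f"altorf_host{j}"] = host
        known = known_set()
        start, end = plant(cds + "TAA", "+")
        annotation.append(
            TranscriptModel(
                f"altgene{j}", chrom, "+", ((start, end),), cds=(start, end - 3)
            )
        )
        alt_start = start + 3 * len(flank_n) + 1
        truth.append(
            TruthRecord(
                f"altorf{j}", "AltORF", chrom, alt_start,
                alt_start + 3 * len(alt), "+", expected,
            )
        )

    genome = {chrom: "".join(pieces)}

    # --- background sweep: absorb residual off-frame products ---
    # Quiet encoding is best-effort; whatever six-frame tryptic peptides
    # remain outside the planted truth become explicit entries of the
    # synthetic background proteome, so the novel space of the finished
    # genome is exactly the planted truth.
    planted = {
        collapse_il(p) for rec in truth for p in rec.novel_peptides
    }
    known = known_set()
    background = set()
    seq = genome[chrom]
    rc = str(Seq(seq).reverse_complement())
    for strand_seq in (seq, rc):
        for offset in range(3):
            n_codons = (len(strand_seq) - offset) // 3
            aa = str(Seq(strand_seq[offset : offset + 3 * n_codons]).translate())
            for pep in _tryptic_in_range(aa, lo, hi):
                key = collapse_il(pep)
                if key not in known and key not in planted:
                    background.add(pep)
    if planted & known:
        raise RuntimeError("planted novel peptide collides with the known proteome")
    for k, pep in enumerate(sorted(background)):
        proteins[f"background{k}"] = pep
    return ToyGenome(genome, proteins, annotation, truth)


# ---------------------------------------------------------------------------
# spectrum bench
# ---------------------------------------------------------------------------

SCENARIOS = ("full", "flanking_deleted", "impostor", "low_intensity_flanking")


@dataclass(frozen=True)
class SpectrumBenchSpec:
    """Composition of the SpectrumAI test bench.

    ``n_per_scenario`` spectra are generated per scenario: "full" carries
    every theoretical b/y ion of the substituted peptide (expected pass);
    "flanking_deleted" removes the four flanking ions (expected fail);
    "impostor" builds the spectrum from the parent sequence and removes
    peaks coinciding with the claimed flanking ions, the mirror-plot
    failure mode of an incorrectly identified substitution; and
    "low_intensity_flanking" keeps the flanking ions at 1% of the
    base intensity (expected fail on the intensity criterion).
    """

    n_per_scenario: int = 10
    peptide_length: tuple = (9, 16)
    base_intensity: float = 1e5
    intensity_cv: float = 0.3
    n_noise_peaks: int = 20
    noise_intensity: float = 1e3
    jitter_ppm: float = 2.0
    tol_ppm: float = 10.0


def _bench_peptide(rng, length: int) -> tuple[str, int, str]:
    """A tryptic peptide, a substitution site and the parent sequence."""
    body = "".join(rng.choice(list("ACDEFGHILMNPSTVWYQ"), size=length - 1))
    peptide = body + ("K" if rng.integers(0, 2) else "R")
    i = int(rng.integers(2, length))  # internal site, avoids terminal modes
    while peptide[i - 2] == "P":
        i = int(rng.integers(2, length))
    ref_choices = [a for a in "ACDEFGHMSTVWY" if a != peptide[i - 1]]
    ref = ref_choices[rng.integers(0, len(ref_choices))]
    parent = peptide[: i - 1] + ref + peptide[i:]
    return peptide, i, parent


def make_spectra(
    spec: SpectrumBenchSpec | None = None,
    mod_config: ModConfig | None = None,
    seed: int = 0,
):
    """Generate the SpectrumAI bench: (PSM, Spectrum, scenario, expected).

    Peaks sit at theoretical b/y m/z (singly charged) with log-normal-ish
    intensity scatter and optional ppm jitter; uniform-m/z noise peaks are
    added everywhere. The expected verdict is fixed by construction.
    """
    spec = spec or SpectrumBenchSpec()
    if spec.jitter_ppm > spec.tol_ppm:
        import warnings

        warnings.warn("jitter exceeds matching tolerance; spectra will not match")
    rng = np.random.default_rng(seed)
    bench = []
    counter = 0
    for scenario in SCENARIOS:
        for _ in range(spec.n_per_scenario):
            length = int(rng.integers(*spec.peptide_length))
            peptide, i, parent = _bench_peptide(rng, length)
            n = len(peptide)
            mods = mod_config.fixed_mods_for(peptide) if mod_config else ()
            claimed_ions = fragment_ions(peptide, mods)
            req = flanking_requirements(n, i, peptide[i - 2])
            flank_labels = req.bond_before | req.bond_after
            flank_mz = {
                ion.mz for ion in claimed_ions
                if (ion.series, ion.index) in flank_labels
            }

            if scenario == "impostor":
                source_mods = mod_config.fixed_mods_for(parent) if mod_config else ()
                peaks = [
                    (ion.mz, spec.base_intensity)
                    for ion in fragment_ions(parent, source_mods)
                    if not any(
                        abs(ion.mz - fm) / fm * 1e6 <= spec.tol_ppm for fm in flank_mz
                    )
                ]
            else:
                peaks = []
                for ion in claimed_ions:
                    is_flank = (ion.series, ion.index) in flank_labels
                    if scenario == "flanking_deleted" and is_flank:
                        continue
                    scale = (
                        0.01
                        if scenario == "low_intensity_flanking" and is_flank
                        else 1.0
                    )
                    peaks.append((ion.mz, scale * spec.base_intensity))

            mz, intensity = [], []
            for m, base in peaks:
                m *= 1 + rng.uniform(-spec.jitter_ppm, spec.jitter_ppm) * 1e-6
                mz.append(m)
                intensity.append(base * abs(1 + rng.normal(0, spec.intensity_cv)))
            noise_mz = rng.uniform(100, 1800, size=spec.n_noise_peaks)
            mz.extend(noise_mz)
            intensity.extend(
                rng.exponential(spec.noise_intensity, size=spec.n_noise_peaks)
            )

            psm = PSM(
                psm_id=f"bench{counter}",
                spectrum_id=f"bench{counter}",
                peptide=peptide,
                sub_pos=i,
                mods=mods,
                score=float(rng.uniform(10, 30)),
            )
            spectrum = Spectrum(psm.spectrum_id, None, 2, np.array(mz), np.array(intensity))
            bench.append((psm, spectrum, scenario, scenario == "full"))
            counter += 1
    return bench


def write_mgf(bench, path) -> None:
    """Write a bench (or any (PSM, Spectrum, ...) rows) to MGF."""
    with open(path, "w") as fh:
        for row in bench:
            psm, spectrum = row[0], row[1]
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={spectrum.spectrum_id}\n")
            fh.write("PEPMASS=0.0\n")
            fh.write("CHARGE=2+\n")
            for m, inten in zip(spectrum.mz, spectrum.intensity):
                fh.write(f"{m:.5f} {inten:.2f}\n")
            fh.write("END IONS\n")


def make_score_mixture(
    n_correct: int = 1000,
    n_incorrect: int = 100,
    n_decoy: int = 1000,
    correct_loc: float = 3.0,
    null_loc: float = 0.0,
    scale: float = 1.0,
    seed: int = 0,
):
    """Seeded PSM score table exercising class-specific FDR recovery.

    Correct targets score ~Normal(correct_loc, scale); incorrect targets
    and decoys both draw from the same Normal(null_loc, scale) null, which
    is the assumption under which decoy counting estimates FDR. Returns a
    pandas DataFrame with truth labels retained.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for k, score in enumerate(rng.normal(correct_loc, scale, n_correct)):
        rows.append((f"t{k}", f"PEPC{k}K", float(score), False, "correct"))
    for k, score in enumerate(rng.normal(null_loc, scale, n_incorrect)):
        rows.append((f"t{n_correct + k}", f"PEPI{k}K", float(score), False, "incorrect"))
    for k, score in enumerate(rng.normal(null_loc, scale, n_decoy)):
        rows.append((f"d{k}", f"PEPD{k}K", float(score), True, "decoy"))
    return pd.DataFrame(
        rows, columns=["psm_id", "peptide", "score", "is_decoy", "truth"]
    )
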