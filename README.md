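# ipaw — integrated proteogenomics analysis workflow

`ipaw` implements the core of an integrated proteogenomics workflow for
discovering and curating novel peptides — peptides absent from the
reference proteome — in shotgun MS/MS data. It is written for
proteogenomics practitioners who need the three stages of such a workflow
as a tested, scriptable library:

1. **Discovery** — construction of the search space: pI-restricted
   six-frame-translation (6FT) peptide databases matched to HiRIEF
   (high-resolution isoelectric focusing) fractions, three-frame
   translations of transcripts, single-amino-acid-variant (SAAV) peptide
   sets from variant catalogs, and reversed-tryptic decoy companions.
2. **Curation** — removal of peptides explainable by the known proteome
   (I=L, deamidation N→D), routing of single-mismatch peptides, and
   **SpectrumAI**: automated inspection of MS2 spectra for fragment ions
   flanking a claimed substitution site.
3. **Validation** — class-specific target-decoy FDR, peptide-to-genome
   mapping with locus grouping and event classification, and scoring
   against orthogonal evidence (RNA-seq read support, conservation,
   coding-potential calls, CAGE/Ribo-seq empirical nulls), plus TMT
   reporter quantitation.

A seeded synthetic-fixtures module generates every input the pipeline
consumes — toy genomes with planted novel coding elements, spectrum
benches with known verdicts, PSM score mixtures — so the whole workflow is
testable at desk scale with no downloads.

## The core algorithms

**Peptide pI.** The net charge of a peptide at pH *p* is the
Henderson–Hasselbalch sum over its ionizable groups,

    z(p) = Σ_basic 1/(1+10^(p−pK_g)) − Σ_acidic 1/(1+10^(pK_g−p)),

with groups neutralized by fixed modifications (TMT on K and the
N-terminus, carbamidomethyl on C) excluded. The pI is the bisection root
of *z* on [0, 14]. HiRIEF fraction numbers convert to experimental pI by
per-strip linear calibrations, e.g. `pI = 0.0676·x + 3.5478` for the
IPG3–10 strip; each fraction database covers its experimental pI interval
widened by the ±0.11 prediction-error margin. The pK constants are
refittable from tightly focused peptides (those in one, or two
consecutive, fractions at PEP < 0.001).

**SpectrumAI.** For a peptide of length *n* with a substitution at
position *i*, the peptide bond N-terminal of the site is witnessed by
b(i−1) or y(n−i+1) and the bond C-terminal of it by b(i) or y(n−i); a
PSM passes only if (a) at least one ion from each side is matched within
10 ppm, and (b) the summed intensity of the matched flanking ions exceeds
the median intensity of all matched fragment ions. When the residue
preceding the site is proline (fragmentation C-terminal of proline being
unfavored), any b or y ion C-terminal of the site suffices. For n = 12,
i = 8 the qualifying pairs are exactly (b7, b8), (y4, y5), (y4, b7),
(y5, b8).

**Class-specific FDR.** Novel and SAAV peptides are classified by
database provenance; targets and decoys matching known tryptic peptides
under I=L or N→D are discarded; then, per class,
`FDR(t) = #decoys ≥ t / #targets ≥ t` with q-values as the running
minimum, using the best-scoring PSM per peptide.

## Worked example

```
$ python examples/01_build_databases.py
toy genome: 9060 bp, 76 known proteins
15 unique novel peptides survive known subtraction
94 peptides removed as exact known matches
example: ATILGNIHLK at chr1:5727(+) predicted pI 8.76
15 reversed-tryptic decoys (0 self-palindromic)
```

The toy genome plants pseudogene copies, an lncRNA ORF, an intergenic
ORF, an in-frame 5'UTR extension and a dual-coded AltORF; the 15 novel
peptides are exactly the planted truth, each assigned to the HiRIEF
fractions whose pI window contains its predicted pI. Curation on the
spectrum bench:

```
$ python examples/03_spectrum_ai.py
        flanking_deleted: fail x10
                    full: pass x10
                impostor: fail x10
  low_intensity_flanking: fail x10
```

Only spectra that contain flanking ions on both sides of the substituted
residue at credible intensity pass; impostor spectra generated from the
parent (unsubstituted) sequence fail because the claimed flanking ions
are absent. Event classification and FDR:

```
$ python examples/05_map_and_classify.py
15 novel peptides mapped to the genome
  5'UTR: 1, AltORF: 1, intergenic: 5, ncRNA: 4, pseudogene: 4

$ python examples/04_class_fdr.py
4316 target peptides at 1% class-specific FDR
true false-discovery proportion among them: 0.009
```

The remaining examples cover pI prediction and pK refitting (`02`),
orthogonal-evidence scoring (`06`) and TMT reporter quantitation (`07`).
A thin CLI mirrors the main entry points:
`ipaw simulate genome`, `ipaw build-6ft`, `ipaw build-vardb`,
`ipaw build-decoy`, `ipaw spectrum-ai`, `ipaw class-fdr`, `ipaw quant`.

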