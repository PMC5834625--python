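# Methods

This note documents the models, parameter choices and numerical decisions
behind `ipaw`, and what the synthetic fixtures do and do not establish
about behavior on real data.

## Peptide chemistry

Digestion is fully tryptic with zero missed cleavages: cleavage after K or
R except when the next residue is proline. Decoys are reversed-tryptic —
the C-terminal residue is kept and the remaining prefix reversed — which
preserves length, composition, and the tryptic C-terminus, and is an
involution. Masses are monoisotopic throughout, pinned in one constants
table (water 18.010565, proton 1.007276, TMT-10plex 229.162932,
carbamidomethyl 57.021464, oxidation 15.994915 Da). Fragment ions are
b/y series only, singly charged by default (`max_charge` configurable);
a/c/x/z ions, neutral losses and isotope envelopes are out of scope.
Peak matching is by relative tolerance (default 10 ppm); when several
peaks fall inside an ion's window the smallest |ppm error| wins, ties
broken by higher intensity, so matching is deterministic. Peptides
containing non-standard residues (X from ambiguous bases, B/Z/U) are
excluded from databases and raise on mass computation: their mass and pI
are undefined.

## Isoelectric point model

Net charge is the standard Henderson–Hasselbalch sum over side chains
(D, E, C, Y acidic; H, K, R basic) and both termini. Groups neutralized
by fixed modifications (TMT on lysine and the alpha-amine,
carbamidomethyl on cysteine) contribute nothing at any pH. The shipped
default pK table is Bjellqvist-style (D 4.05, E 4.45, C 9.0, Y 10.0,
H 5.98, K 10.0, R 12.0, N-term 7.5, C-term 3.55); all values are loadable
from TSV so a refitted set can be substituted. Position-dependent pK
adjustments near termini are not applied (no hook enabled by default).

pI is found by bisection on [0, 14] to |charge| < 1e−4 within 100
iterations. Degenerate peptides whose charge curve has no sign change are
clamped: net-negative everywhere → 0, net-positive everywhere → 14,
since bisection requires a bracketing interval.

pK refitting minimizes the mean absolute difference between experimental
and predicted pI by Nelder–Mead over a selected subset of pK values, with
seeded random restarts, and never returns a table worse on the training
set than its starting point. The objective is evaluated through a
vectorized bisection (60 fixed iterations over the whole training matrix)
so a fit of a few constants on a few hundred peptides takes seconds.
Training requires ≥ 100 pairs spanning ≥ 2 pI units; tightly focused
peptides are those observed in exactly one fraction or two consecutive
fractions with posterior error probability below 0.001.

Strip calibrations are linear (`pI = slope·fraction + intercept`) with
defaults for IPG3–10 (0.0676, 3.5478), IPG3.7–4.9 (0.0174, 3.5959),
IPG6–9 (0.0336, 6.1159) and IPG6–11 (−0.0762, 10.3936; this strip runs
alkaline-to-acidic). Run-to-run offsets are removed by subtracting the
per-strip median delta pI (experimental − predicted) computed from
high-confidence peptides; the median, not the mean, so outliers cannot
shift the center.

## Database construction

Six-frame translation produces three forward and three reverse-complement
frames per sequence; segments split at stop codons (the stop is not
translated) and codons containing ambiguous bases become X. Coordinates
are 0-based half-open internally; GTF/GFF-style output is 1-based
inclusive. The 6FT pipeline is translate → digest → drop X-containing →
subtract known (exact under I=L) → deduplicate keeping every genomic
locus → length filter (8–30 residues) → predict pI → assign to fractions.
A peptide enters every fraction whose experimental window, widened by the
±0.11 pI margin on both sides, contains its predicted pI; window edges
are inclusive, so a boundary peptide may enter two neighboring databases
— the margin exists precisely to tolerate prediction error. Each
fraction database is appended with the full canonical proteome as
whole-protein entries for the downstream search engine to digest.

Known-peptide subtraction collapses I to L before comparison.
Deamidation-explainable peptides (equal to a known peptide after mapping
N→D on both sides) are flagged but retained at build time; the FDR stage
discards them. Mapping N→D on both sides is slightly conservative — it
also removes the reverse (D observed where the known peptide has D and
the query N), which cannot arise from deamidation — erring toward fewer
false novelties.

SAAV peptides are built by substituting the variant residue into the
parent protein and re-digesting the mutated protein, so substitutions
that create or destroy cleavage sites yield the correct tryptic products;
only peptides containing the substituted position are kept, with the
within-peptide position recorded for curation. I↔L substitutions are
emitted but flagged indistinguishable.

## SpectrumAI

A single-substitution PSM passes when (a) the flanking-ion requirement is
met by peaks matched within 10 ppm and (b) the summed intensity of all
matched flanking ions strictly exceeds the median intensity of the
comparison population. Interpretation choices:

- The intensity median is taken over the **matched** theoretical b/y ions
  of the PSM, not all spectrum peaks ("fragmentation ions" read as
  assigned ions); an all-peaks mode is available (`median_mode`).
- All matched flanking ions are pooled for the intensity sum rather than
  scoring only the best single pair.
- Terminal substitutions (i = 1 or i = n) have only one internal flanking
  bond; that single bond is required.
- The proline exception accepts any b_j with j ≥ i or any y_k with
  k ≤ n − i (any bond at or C-terminal of the site).
- Intensity ties fail (strict inequality).

A peptide passes when at least one of its PSMs passes. Novel peptides
without an annotated substitution are routed by a single-mismatch search
against the I/L-collapsed known tryptic index: Hamming distance 0 means
not novel; distance exactly 1 yields the parent and site (deterministic
lexicographic first match); anything else stays in the multi-mismatch
class and bypasses SpectrumAI.

Known limitation: an impostor whose spectrum comes from the known
sequence differing only as N→D still satisfies criterion (a), because one
qualifying pair — (y(n−i), b(i−1)) — does not cover the substituted
residue at all. The equivalence discard at the FDR stage is the guard for
this case, and the test suite documents it explicitly.

## Class-specific FDR

The workflow searches target and decoy databases separately; this module
never assumes a concatenated search. After discarding target and decoy
matches to known peptides under the equivalences, per-class FDR at
threshold t is decoys ≥ t over targets ≥ t (orientation configurable for
E-value-like scores), computed on the best PSM per peptide; q-values are
the running minimum from the strictest threshold. Score ties count decoys
before targets, which is conservative. The decoy-counting estimate is
unbiased when decoy scores and incorrect-target scores draw from the same
null — exactly the condition the score-mixture generator reproduces
(equal numbers of incorrect targets and decoys from one null
distribution).

## Genome mapping and event classification

Transcript-relative peptides project to spliced genomic blocks through
the exon structure; minus-strand transcripts map right-to-left, and the
round trip (extract, reverse-complement on minus, translate) must
reproduce the peptide. Loci are grouped by single-linkage clustering of
block-span hulls with a 10 kb gap; group identifiers derive from the
leftmost coordinate, so grouping is order-invariant, and locus counts are
non-increasing in the gap. Multi-mapping peptides (more than one exact
genomic occurrence across all six frames) are flagged and deprioritized,
not deleted; splice-junction-only peptides (zero contiguous occurrences)
are flagged as such.

Event classification applies a fixed precedence — pseudogene exon
overlap, ncRNA exon overlap, out-of-frame CDS overlap (AltORF), 5'UTR,
3'UTR, exon extension, intronic, intergenic — chosen so that the most
specific annotation wins; the order is configurable since annotation
conventions differ. UTR sidedness is strand-aware. ORF-context scanning
walks in-frame upstream of a contiguous locus to the nearest stop,
reporting ATG and the nine near-cognate codons (one base from ATG) with
their surrounding nucleotide context, and finds the first in-frame
downstream stop; Kozak strong/moderate classification is deliberately not
scored, only the context string is reported.

## Orthogonal evidence

An RNA-seq read supports a peptide region when it is uniquely aligned
(hit-count tag 1 when present, else a mapping-quality floor), has at most
one mismatch within the region itself (mismatches located via the MD
tag; reads with no mismatch evidence are skipped and counted), and is
properly paired when paired; spliced alignments whose aligned segments
miss the region never count. Tightening any criterion can only decrease
the count.

Conservation is the arithmetic mean of per-base scores over a region with
the covered fraction reported; a region with no data returns an explicit
no-data marker, never 0, since 0 is a meaningful conservation value.
Coding-potential calls over per-frame tracks are "coding" if any frame's
mean exceeds the threshold (default 0), "non-coding" if all covered
frames stay at or below it, "no-call" with no data. Random-set
comparisons sample 1000 pool entries without replacement (seeded) and
report quartiles, Tukey whiskers (upper = min(max(x), Q3 + 1.5·IQR)) and
a two-sided rank-sum p-value.

CAGE/Ribo-seq support uses an empirical null: 10,000 random genomic
intervals with lengths resampled from the observed peptide-length
distribution; the support threshold is the 95th percentile of the null
interval signal (the percentile is a package choice; a locus is
supported when its signal strictly exceeds it, giving a ~5% flag rate on
null data). The CAGE window extends 500 bp upstream of the peptide,
strand-aware (upstream of a minus-strand peptide is genomically
rightward).

## Reporter quantitation

TMT-10plex reporter m/z values are pinned from the vendor's monoisotopic
table. Extraction takes the nearest peak within a 10 ppm window per
channel and errors out if the tolerance makes adjacent channel windows
overlap. Ratios are taken against a configurable reference channel.
Normalization divides each channel by the median ratio of the canonical
peptide table — never the novel table's own medians, because the novel
set is small and must not define its own center; channels with a zero or
missing canonical median are flagged and left unnormalized. Isotope
impurity correction and protein-level summarization are out of scope.

## Synthetic fixtures

The toy genome (default ~9 kb, well under the ≤500 kb budget that keeps
the full pipeline in seconds) plants, on alternating strands: canonical
intronless genes defining the known proteome; pseudogene copies of
parents with protein-level point substitutions at a 5% rate and no
indels, guaranteeing unique tryptic peptides; an lncRNA with an embedded
ORF; an intergenic ORF; an N-terminal extension with a near-cognate CTG
start whose annotation begins downstream (so the extension is in-frame
5'UTR); and an AltORF whose peptide is dual-coded into the +1 frame of a
host gene by fixing the shifted-frame codons and deriving a stop-free
frame-0 host.

Two constructions make recovery exact rather than statistical.
Intergenic spacers are CTAG repeats: the repeat is its own reverse
complement and places a stop codon in every reading frame on both strands
within 12 nt, so spacers cannot contribute peptides. Element coding
sequences are "quiet-encoded": a greedy codon chooser seeds stop codons
into the five non-coding frames (tracking which frame has gone longest
without one), then a local search swaps synonymous codons to shrink
remaining off-frame tryptic products, each element checked in its exact
flanking context. Some off-frame products admit no synonymous fix, so
the assembler finally absorbs any residual six-frame peptide outside the
planted truth into the synthetic known proteome as explicit background
entries. The planted novel set is therefore exactly the recoverable
novel set, which is what the round-trip and recovery tests assert.

The spectrum bench generates b/y peaks at theoretical m/z with log-normal
intensity scatter, ≤2 ppm jitter against a 10 ppm matching tolerance, and
uniform-m/z noise peaks, in four scenarios: full coverage (expected
pass), flanking ions deleted (fail), parent-sequence impostor with peaks
coinciding with the claimed flanking ions removed — the mirror-plot
failure mode of an incorrect substitution — (fail), and flanking ions at
1% intensity (fail on the intensity criterion). The score mixture draws
correct-target scores from a shifted normal and incorrect-target and
decoy scores from one shared null, with truth labels retained.

What the fixtures do **not** emulate: chimeric spectra, co-eluting
isobaric species, retention-time structure, isotope envelopes, real
codon-usage bias, splice junctions inside peptides, and genome-scale
repeat content. Passing tests therefore demonstrate algorithmic
correctness under clean, fully-specified conditions — not end-to-end
performance on real LC-MS/MS data, where search-engine behavior and
chemical artifacts dominate.

## Problem sizes

The default test suite runs the toy genome at ~9 kb with ten planted
elements, the spectrum bench at 40 PSMs, FDR recovery at n = 5000 targets
over 20 seeds, pK recovery on 200 peptides over three constants, and the
empirical null at 10,000 intervals — sizes chosen so the full suite
completes in well under a minute per module while keeping every estimate's
sampling error far below its test tolerance.
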