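"""Orthogonal evidence scoring for novel peptide loci.

Validation-stage support: RNA-seq read counting under uniqueness/mismatch/
pairing criteria, mean per-base conservation, PhyloCSF-style coding calls
over six frames, and CAGE/Ribo-seq support against an empirical null of
random genomic intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu

__all__ = [
    "ReadSupportCriteria",
    "SupportVector",
    "ScoreTrack",
    "count_supporting_reads",
    "mean_conservation",
    "compare_random_sets",
    "classify_phylocsf",
    "empirical_null_threshold",
    "cage_window",
]

NO_DATA = None  # sentinel distinct from a genuine score of 0


@dataclass(frozen=True)
class ReadSupportCriteria:
    """Which alignments count as mRNA-level evidence for a peptide region.

    A read supports a peptide region when it (1) aligns uniquely, (2) has
    at most ``max_mismatch_in_region`` mismatches inside the region itself,
    and (3) is properly paired when from a paired-end run. Spliced reads
    whose aligned segments skip the region never count.
    """

    require_unique: bool = True
    max_mismatch_in_region: int = 1
    require_proper_pair_if_paired: bool = True
    exclude_gap_spanning: bool = True
    mapq_floor: int = 255  # uniqueness fallback when no hit-count tag


@dataclass
class SupportVector:
    """Per-peptide orthogonal evidence, continuous and discretized."""

    peptide: str
    rna_read_count: int = 0
    mean_conservation: float | None = NO_DATA
    phylocsf_call: str = "no-call"
    cage_support: bool = False
    ribo_support: bool = False
    has_neighbor_peptide: bool = False

    def binary(self) -> dict:
        return {
            "rna": int(self.rna_read_count > 0),
            "conservation": int((self.mean_conservation or 0) > 0.5),
            "phylocsf": int(self.phylocsf_call == "coding"),
            "cage": int(self.cage_support),
            "ribo": int(self.ribo_support),
            "neighbor": int(self.has_neighbor_peptide),
        }


class ScoreTrack:
    """Per-base score arrays per chromosome; NaN marks missing data."""

    def __init__(self, arrays: dict):
        self.arrays = {c: np.asarray(a, dtype=float) for c, a in arrays.items()}

    @classmethod
    def from_bedgraph(cls, path, chrom_sizes: dict) -> "ScoreTrack":
        arrays = {c: np.full(size, np.nan) for c, size in chrom_sizes.items()}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("track", "#", "browser")):
                    continue
                chrom, start, end, value = line.split()[:4]
                if chrom in arrays:
                    arrays[chrom][int(start) : int(end)] = float(value)
        return cls(arrays)

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        arr = self.arrays.get(chrom)
        if arr is None:
            return np.full(max(end - start, 0), np.nan)
        start = max(start, 0)
        end = min(end, len(arr))
        return arr[start:end] if end > start else np.array([])

    def interval_sum(self, chrom: str, start: int, end: int) -> float:
        vals = self.values(chrom, start, end)
        return float(np.nansum(vals)) if vals.size else 0.0

    @property
    def chrom_sizes(self) -> dict:
        return {c: len(a) for c, a in self.arrays.items()}


def _read_region_mismatches(read, start: int, end: int) -> int | None:
    """Mismatches of an aligned read inside [start, end); None if unknowable."""
    try:
        pairs = read.get_aligned_pairs(with_seq=True)
    except ValueError:
        pairs = None
    if pairs:
        n = 0
        informative = False
        for qpos, rpos, ref_base in pairs:
            if rpos is None or qpos is None or not (start <= rpos < end):
                continue
            if ref_base is None:
                continue
            informative = True
            if ref_base.islower():
                n += 1
        if informative:
            return n
    # fall back to the whole-read edit distance when no MD tag is present
    if read.has_tag("NM"):
        return int(read.get_tag("NM"))
    return None


def count_supporting_reads(
    alignments,
    chrom: str,
    start: int,
    end: int,
    criteria: ReadSupportCriteria | None = None,
) -> tuple[int, dict]:
    """Count alignments supporting a peptide region under the criteria.

    ``alignments`` is an iterable of pysam AlignedSegment (e.g. from
    ``AlignmentFile.fetch``). Returns (count, skip-counter dict).
    """
    criteria = criteria or ReadSupportCriteria()
    count = 0
    skipped = {"unmapped": 0, "wrong_chrom": 0, "no_overlap": 0, "multimapped": 0,
               "mismatches": 0, "not_proper_pair": 0, "no_mismatch_info": 0}
    for read in alignments:
        if read.is_unmapped:
            skipped["unmapped"] += 1
            continue
        if read.reference_name != chrom:
            skipped["wrong_chrom"] += 1
            continue
        blocks = read.get_blocks()
        overlapping = [b for b in blocks if b[0] < end and b[1] > start]
        if not overlapping:
            # includes spliced reads whose gap spans the region
            skipped["no_overlap"] += 1
            continue
        if criteria.require_unique:
            if read.has_tag("NH"):
                if read.get_tag("NH") != 1:
                    skipped["multimapped"] += 1
                    continue
            elif read.mapping_quality < criteria.mapq_floor:
                skipped["multimapped"] += 1
                continue
        if criteria.require_proper_pair_if_paired and read.is_paired:
            if not read.is_proper_pair:
                skipped["not_proper_pair"] += 1
                continue
        mismatches = _read_region_mismatches(read, start, end)
        if mismatches is None:
            skipped["no_mismatch_info"] += 1
            warnings.warn(f"read {read.query_name}: no mismatch evidence, skipped")
            continue
        if mismatches > criteria.max_mismatch_in_region:
            skipped["mismatches"] += 1
            continue
        count += 1
    return count, skipped


def mean_conservation(track: ScoreTrack, chrom: str, start: int, end: int):
    """Mean per-base conservation over a region.

    Returns (mean, coverage_fraction); mean is the no-data marker (None)
    when no base in the region has a score — never silently 0, since 0 is a
    meaningful conservation value.
    """
    if end <= start:
        raise ValueError("region must be non-empty")
    vals = track.values(chrom, start, end)
    covered = np.isfinite(vals)
    coverage = float(covered.sum() / (end - start))
    if not covered.any():
        return NO_DATA, 0.0
    return float(np.nanmean(vals)), coverage


def _box_stats(x: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    return {
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "upper_whisker": float(min(np.max(x), q3 + 1.5 * iqr)),
        "lower_whisker": float(max(np.min(x), q1 - 1.5 * iqr)),
    }


def compare_random_sets(novel_scores, pool_scores, n: int = 1000, seed: int = 0) -> dict:
    """Compare novel-locus scores with a random annotation sample.

    Draws ``n`` pool entries without replacement (seeded; the whole pool
    with a warning when it is smaller than n), reports box statistics with
    Tukey whiskers for both sets and a two-sided rank-sum p-value.
    """
    novel = np.asarray(list(novel_scores), dtype=float)
    pool = np.asarray(list(pool_scores), dtype=float)
    rng = np.random.default_rng(seed)
    if len(pool) < n:
        warnings.warn(f"pool of {len(pool)} smaller than n={n}; using all")
        sample = pool.copy()
    else:
        sample = rng.choice(pool, size=n, replace=False)
    stat, p = mannwhitneyu(novel, sample, alternative="two-sided")
    return {
        "novel": _box_stats(novel),
        "random": _box_stats(sample),
        "p_value": float(p),
        "n_random": int(len(sample)),
    }


def classify_phylocsf(
    frame_tracks: dict,
    chrom: str,
    start: int,
    end: int,
    threshold: float = 0.0,
) -> str:
    """Coding-potential call over up to six per-frame score tracks.

    "coding" when any frame's mean score exceeds the threshold,
    "non-coding" when every covered frame stays at or below it, "no-call"
    when no frame has data over the region.
    """
    any_data = False
    for track in frame_tracks.values():
        mean, _cov = mean_conservation(track, chrom, start, end)
        if mean is NO_DATA:
            continue
        any_data = True
        if mean > threshold:
            return "coding"
    return "non-coding" if any_data else "no-call"


def cage_window(start: int, end: int, strand: str, upstream: int = 500) -> tuple:
    """Extend a peptide region upstream (strand-aware) for CAGE evaluation.

    Upstream of a minus-strand peptide lies genomically rightward.
    """
    if strand == "-":
        return (start, end + upstream)
    return (max(0, start - upstream), end)


@dataclass
class EmpiricalNull:
    """Null distribution of interval signal from random genomic placement."""

    threshold: float
    signals: np.ndarray

    def is_supported(self, signal: float) -> bool:
        return signal > self.threshold


def empirical_null_threshold(
    track: ScoreTrack,
    lengths,
    n: int = 10000,
    seed: int = 0,
    percentile: float = 95.0,
) -> EmpiricalNull:
    """Signal threshold from random genomic intervals.

    Samples ``n`` intervals with lengths drawn with replacement from the
    observed peptide-length distribution and placements uniform over the
    genome, then takes the given percentile (default 95) of the interval
    signal sums. A locus whose signal exceeds the threshold counts as
    supported.
    """
    lengths = np.asarray(list(lengths), dtype=int)
    if lengths.size == 0:
        raise ValueError("lengths list must be non-empty")
    sizes = track.chrom_sizes
    chroms = sorted(sizes)
    weights = np.array([sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    rng = np.random.default_rng(seed)
    signals = np.empty(n)
    for k in range(n):
        length = int(rng.choice(lengths))
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        hi = max(sizes[chrom] - length, 1)
        start = int(rng.integers(0, hi))
        signals[k] = track.interval_sum(chrom, start, start + length)
    return EmpiricalNull(float(np.percentile(signals, percentile)), signals)
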