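"""Orthogonal evidence: RNA-seq criteria, conservation, coding calls, nulls."""

import numpy as np
import pysam
import pytest

from ipaw.orthogonal_support import (
    NO_DATA,
    ReadSupportCriteria,
    ScoreTrack,
    cage_window,
    classify_phylocsf,
    compare_random_sets,
    count_supporting_reads,
    empirical_null_threshold,
    mean_conservation,
)

HEADER = pysam.AlignmentHeader.from_dict(
    {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 100000}]}
)


def _read(
    name="r", start=1000, cigar="50M", nh=1, nm=0, paired=False, proper=True,
    mapq=60,
):
    a = pysam.AlignedSegment(HEADER)
    a.query_name = name
    a.reference_id = 0
    a.reference_start = start
    a.cigarstring = cigar
    n_bases = sum(
        length for op, length in a.cigartuples if op in (0, 1, 4)
    )
    a.query_sequence = "A" * n_bases
    a.mapping_quality = mapq
    a.set_tag("NH", nh)
    a.set_tag("NM", nm)
    if paired:
        a.flag |= 0x1
        if proper:
            a.flag |= 0x2
    return a


REGION = ("chr1", 1010, 1040)


def test_unique_single_mismatch_read_counts():
    count, _ = count_supporting_reads([_read()], *REGION)
    assert count == 1
    count, _ = count_supporting_reads([_read(nm=1)], *REGION)
    assert count == 1


def test_multimapped_read_excluded():
    count, skipped = count_supporting_reads([_read(nh=2)], *REGION)
    assert count == 0 and skipped["multimapped"] == 1


def test_two_mismatches_excluded():
    count, skipped = count_supporting_reads([_read(nm=2)], *REGION)
    assert count == 0 and skipped["mismatches"] == 1


def test_improper_pair_excluded():
    count, skipped = count_supporting_reads(
        [_read(paired=True, proper=False)], *REGION
    )
    assert count == 0 and skipped["not_proper_pair"] == 1
    count, _ = count_supporting_reads([_read(paired=True, proper=True)], *REGION)
    assert count == 1


def test_spliced_read_gap_over_region_excluded():
    # aligned blocks [980,1000) and [1100,1120): the gap spans the region
    spliced = _read(start=980, cigar="20M100N20M")
    count, skipped = count_supporting_reads([spliced], *REGION)
    assert count == 0 and skipped["no_overlap"] == 1


def test_criteria_tightening_is_monotone():
    reads = [
        _read("a"),
        _read("b", nh=2),
        _read("c", nm=2),
        _read("d", paired=True, proper=False),
        _read("e", nm=1),
    ]
    loose = ReadSupportCriteria(
        require_unique=False, max_mismatch_in_region=10,
        require_proper_pair_if_paired=False,
    )
    tight = ReadSupportCriteria()
    n_loose, _ = count_supporting_reads(reads, *REGION, criteria=loose)
    n_tight, _ = count_supporting_reads(reads, *REGION, criteria=tight)
    assert n_loose >= n_tight
    assert (n_loose, n_tight) == (5, 2)


def test_mean_conservation_and_no_data():
    track = ScoreTrack({"chr1": np.full(1000, 0.5)})
    mean, cov = mean_conservation(track, "chr1", 100, 200)
    assert mean == pytest.approx(0.5) and cov == 1.0

    half = np.concatenate([np.ones(50), np.zeros(50)])
    track2 = ScoreTrack({"chr1": half})
    mean2, _ = mean_conservation(track2, "chr1", 0, 100)
    assert mean2 == pytest.approx(0.5)

    empty = ScoreTrack({"chr1": np.full(1000, np.nan)})
    mean3, cov3 = mean_conservation(empty, "chr1", 100, 200)
    assert mean3 is NO_DATA and cov3 == 0.0


def test_split_region_recombines_as_weighted_mean():
    rng = np.random.default_rng(0)
    track = ScoreTrack({"chr1": rng.uniform(0, 1, 1000)})
    whole, _ = mean_conservation(track, "chr1", 100, 400)
    left, _ = mean_conservation(track, "chr1", 100, 200)
    right, _ = mean_conservation(track, "chr1", 200, 400)
    assert whole == pytest.approx((left * 100 + right * 200) / 300)


def test_box_whisker_formula():
    x = np.arange(0, 1.05, 0.1)
    out = compare_random_sets(x, np.tile(x, 100), n=100, seed=0)
    stats = out["novel"]
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    assert stats["upper_whisker"] == pytest.approx(min(x.max(), q3 + 1.5 * iqr))
    assert stats["lower_whisker"] == pytest.approx(max(x.min(), q1 - 1.5 * iqr))


def test_identical_distributions_not_significant():
    rng = np.random.default_rng(1)
    pool = rng.uniform(0, 1, 5000)
    out = compare_random_sets(pool[:500], pool, n=1000, seed=2)
    assert out["p_value"] > 0.05


def test_random_set_sampling_deterministic():
    pool = np.arange(2000, dtype=float)
    a = compare_random_sets(pool[:100], pool, n=500, seed=3)
    b = compare_random_sets(pool[:100], pool, n=500, seed=3)
    assert a == b


def test_phylocsf_calls():
    coding = ScoreTrack({"chr1": np.full(1000, 10.0)})
    noncoding = ScoreTrack({"chr1": np.full(1000, -5.0)})
    nodata = ScoreTrack({"chr1": np.full(1000, np.nan)})
    assert classify_phylocsf(
        {1: coding, 2: noncoding}, "chr1", 10, 100
    ) == "coding"
    assert classify_phylocsf(
        {1: noncoding, 2: noncoding}, "chr1", 10, 100
    ) == "non-coding"
    assert classify_phylocsf({1: nodata}, "chr1", 10, 100) == "no-call"


def test_cage_window_strand_aware():
    assert cage_window(1000, 1100, "+", 500) == (500, 1100)
    assert cage_window(1000, 1100, "-", 500) == (1000, 1600)
    assert cage_window(100, 200, "+", 500) == (0, 200)


def test_empirical_null_zero_track():
    track = ScoreTrack({"chr1": np.zeros(10000)})
    null = empirical_null_threshold(track, [30], n=500, seed=0)
    assert null.threshold == 0.0
    assert null.is_supported(1.0) and not null.is_supported(0.0)


def test_empirical_null_flags_planted_hotspot():
    arr = np.zeros(20000)
    arr[5000:5100] = 50.0
    track = ScoreTrack({"chr1": arr})
    null = empirical_null_threshold(track, [60], n=2000, seed=1)
    assert null.is_supported(track.interval_sum("chr1", 5000, 5060))
    assert not null.is_supported(track.interval_sum("chr1", 15000, 15060))


def test_empirical_null_deterministic():
    rng = np.random.default_rng(2)
    track = ScoreTrack({"chr1": rng.uniform(0, 1, 20000)})
    a = empirical_null_threshold(track, [30, 60], n=1000, seed=5)
    b = empirical_null_threshold(track, [30, 60], n=1000, seed=5)
    assert np.array_equal(a.signals, b.signals)


def test_bedgraph_reader(tmp_path):
    path = tmp_path / "track.bedGraph"
    path.write_text("track type=bedGraph\nchr1\t0\t10\t0.5\nchr1\t10\t20\t1.0\n")
    track = ScoreTrack.from_bedgraph(path, {"chr1": 30})
    assert track.interval_sum("chr1", 0, 20) == pytest.approx(15.0)
    mean, cov = mean_conservation(track, "chr1", 0, 30)
    assert cov == pytest.approx(20 / 30)
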