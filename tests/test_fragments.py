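"""Fragment I/O, filtering, pair merging and length-mode detection."""

import numpy as np
import pandas as pd
import pytest

import cenchrom as cc
from cenchrom.fragments import FragmentSet, merge_pairs, quality_filter, length_modes, load_fragments


# ---------------------------------------------------------------- loading
def test_bed_record_parsed_with_score_as_mapq(tmp_path):
    p = tmp_path / "x.bed"
    p.write_text("chr1\t100\t300\t.\t60\n")
    fs = load_fragments(p)
    row = fs.df.iloc[0]
    assert (row["chrom"], row["start"], row["end"], row["mapq"]) == ("chr1", 100, 300, 60)


def test_empty_bed_gives_empty_set(tmp_path):
    p = tmp_path / "x.bed"
    p.write_text("")
    assert len(load_fragments(p)) == 0


def test_malformed_bed_reports_line_number(tmp_path):
    p = tmp_path / "x.bed"
    p.write_text("chr1\t100\t300\nchr1\tnotanumber\t5\n")
    with pytest.raises(ValueError, match="line 2"):
        load_fragments(p)


def test_sam_proper_pair_collapsed_to_outer_span(tmp_path):
    # mates [100,200) and [250,350) -> fragment [100,350)
    sam = tmp_path / "x.sam"
    sam.write_text(
        "@HD\tVN:1.6\tSO:coordinate\n"
        "@SQ\tSN:chr1\tLN:1000\n"
        "r1\t99\tchr1\t101\t60\t100M\t=\t251\t250\t" + "A" * 100 + "\t*\tNM:i:0\n"
        "r1\t147\tchr1\t251\t60\t100M\t=\t101\t-250\t" + "A" * 100 + "\t*\tNM:i:0\n"
    )
    fs = load_fragments(sam, fmt="bam")
    assert len(fs) == 1
    row = fs.df.iloc[0]
    assert (row["start"], row["end"]) == (100, 350)


# ---------------------------------------------------------------- filtering
def test_quality_filter_thresholds():
    df = pd.DataFrame({
        "chrom": ["c"] * 4,
        "start": [0, 0, 0, 0],
        "end": [147, 147, 147, 250],
        "mapq": [19.0, 60.0, 60.0, 60.0],
        "nm": [0.0, 0.0, 2.0, 0.0],
    })
    res = quality_filter(FragmentSet(df))
    # mapq 19 removed, 2 mismatches removed, length 250 removed
    assert len(res.fragments) == 1
    assert res.removed["mapq"] == 1 and res.removed["mismatch"] == 1 and res.removed["length"] == 1


def test_length_filter_enumerated():
    lengths = np.arange(90, 291, 20)  # 90,110,...,290
    df = pd.DataFrame({"chrom": "c", "start": 0, "end": lengths, "mapq": 60.0, "nm": 0.0})
    res = quality_filter(FragmentSet(df))
    assert sorted(res.fragments.lengths) == [110, 130, 150, 170, 190]


def test_quality_filter_idempotent(rng):
    df = pd.DataFrame({
        "chrom": "c",
        "start": rng.integers(0, 1000, 200),
        "end": 0,
        "mapq": rng.integers(0, 61, 200).astype(float),
        "nm": rng.integers(0, 3, 200).astype(float),
    })
    df["end"] = df["start"] + rng.integers(80, 260, 200)
    once = quality_filter(FragmentSet(df)).fragments
    twice = quality_filter(once).fragments
    pd.testing.assert_frame_equal(once.df, twice.df)


# ---------------------------------------------------------------- pair merging
def test_merge_pairs_overlap_and_gap():
    pairs = pd.DataFrame({
        "chrom1": ["c", "c", "c"], "start1": [0, 0, 0], "end1": [100, 100, 100],
        "chrom2": ["c", "c", "d"], "start2": [60, 150, 60], "end2": [160, 250, 160],
    })
    res = merge_pairs(pairs)
    assert len(res.fragments) == 1  # gap pair and chimeric pair unmerged
    assert res.fragments.df.iloc[0]["end"] == 160
    assert res.n_unmerged == 2


def test_merge_rate_one_when_reads_cover_fragment(rng):
    # 147-bp fragments with 100-bp reads: 2*100 > 147, mates always overlap
    starts = rng.integers(0, 10_000, 100)
    pairs = pd.DataFrame({
        "chrom1": "c", "start1": starts, "end1": starts + 100,
        "chrom2": "c", "start2": starts + 47, "end2": starts + 147,
    })
    res = merge_pairs(pairs)
    assert res.merge_rate == 1.0
    assert (res.fragments.lengths == 147).all()


def test_merge_pairs_idempotent_on_fragment_output(rng):
    starts = rng.integers(0, 10_000, 50)
    pairs = pd.DataFrame({
        "chrom1": "c", "start1": starts, "end1": starts + 100,
        "chrom2": "c", "start2": starts + 40, "end2": starts + 140,
    })
    once = merge_pairs(pairs).fragments
    twice = merge_pairs(once).fragments
    pd.testing.assert_frame_equal(once.df, twice.df)


# ---------------------------------------------------------------- length modes
def test_single_length_single_mode():
    df = pd.DataFrame({"chrom": "c", "start": 0, "end": np.full(100, 147)})
    dist = length_modes(FragmentSet(df))
    assert dist.top_modes(3) == [147]
    assert np.isclose(dist.fractions.sum(), 1.0)


def test_planted_mixture_modes_recovered(rng):
    comp = rng.choice([147, 133, 123], p=[0.7, 0.2, 0.1], size=50_000)
    lengths = np.rint(rng.normal(comp, 1.0)).astype(int)
    df = pd.DataFrame({"chrom": "c", "start": 0, "end": lengths})
    dist = length_modes(FragmentSet(df))
    top3 = sorted(dist.top_modes(3))
    assert all(abs(a - b) <= 1 for a, b in zip(top3, [123, 133, 147]))


def test_equal_modes_tie_broken_to_smaller_length():
    df = pd.DataFrame({"chrom": "c", "start": 0, "end": [140] * 50 + [150] * 50})
    dist = length_modes(FragmentSet(df))
    assert dist.top_modes(2) == [140, 150]


def test_empty_set_rejected():
    with pytest.raises(ValueError):
        length_modes(FragmentSet(pd.DataFrame(columns=["chrom", "start", "end"])))
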