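"""Fragment table parsing, alignment extraction, dedup, filters, windows."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fragmedip import (
    GenomeLayout,
    WindowGrid,
    deduplicate,
    filter_size_range,
    fragments_from_paired_alignments,
    read_fragment_table,
    write_fragment_table,
)
from fragmedip.fragment_io import (
    FragmentTableError,
    assign_to_windows,
    fragment_window_ids,
    make_fragment_set,
    window_counts,
)

from conftest import fragments_of_lengths, prep


# ---------------------------------------------------------------------------
# fragment tables
# ---------------------------------------------------------------------------


def test_read_fragment_table_identity(tmp_path):
    p = tmp_path / "frags.tsv"
    p.write_text("chr1\t100\t267\nchr1\t500\t640\nchr2\t0\t180\n")
    fs = read_fragment_table(p, "S1", "INPUT")
    assert len(fs) == 3
    assert list(fs.frame["chrom"]) == ["chr1", "chr1", "chr2"]
    assert list(fs.lengths) == [167, 140, 180]
    assert list(fs.frame["barcode"]) == ["", "", ""]


def test_read_fragment_table_preserves_barcode(tmp_path):
    p = tmp_path / "frags.tsv"
    p.write_text("chr1\t100\t267\tAAGGCTTA\n")
    fs = read_fragment_table(p, "S1", "IP")
    assert fs.frame.loc[0, "barcode"] == "AAGGCTTA"


@pytest.mark.parametrize("content,match", [
    ("chr1\t500\t500\n", "line 1"),                 # degenerate interval
    ("chr1\t100\t267\nchr1\t9\t2\n", "line 2"),     # end < start
    ("chr1\tx\t267\n", "line 1"),                   # non-integer
])
def test_read_fragment_table_malformed(tmp_path, content, match):
    p = tmp_path / "bad.tsv"
    p.write_text(content)
    with pytest.raises(FragmentTableError, match=match):
        read_fragment_table(p, "S1", "INPUT")


def test_fragment_table_round_trip(tmp_path, small_cohort):
    fs = small_cohort.samples[0].input_set
    p = tmp_path / "rt.tsv"
    write_fragment_table(fs, p)
    back = read_fragment_table(p, fs.sample_id, fs.library)
    pd.testing.assert_frame_equal(back.frame, fs.frame)


# ---------------------------------------------------------------------------
# paired alignments
# ---------------------------------------------------------------------------

SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:100000\n"


def _sam_line(name, flag, pos, mapq, cigar, pnext, tlen, tags=""):
    base = (f"{name}\t{flag}\tchr1\t{pos}\t{mapq}\t{cigar}\t=\t{pnext}\t"
            f"{tlen}\t*\t*")
    return base + (f"\t{tags}" if tags else "") + "\n"


@pytest.fixture()
def sam_path(tmp_path):
    lines = [
        # proper pair spanning [1000, 1167) -> fragment of length 167
        _sam_line("PAIR1", 99, 1001, 60, "75M", 1093, 167, "RX:Z:AAGGCTTA"),
        _sam_line("PAIR1", 147, 1093, 60, "75M", 1001, -167, "RX:Z:AAGGCTTA"),
        # insert of 15 bp -> dropped under min_insert=20
        _sam_line("PAIR2", 99, 2001, 60, "10M", 2006, 15),
        _sam_line("PAIR2", 147, 2006, 60, "10M", 2001, -15),
        # proper-pair flag not set -> dropped
        _sam_line("PAIR3", 97, 3001, 60, "75M", 3093, 167),
        _sam_line("PAIR3", 145, 3093, 60, "75M", 3001, -167),
        # low mapping quality -> dropped ("uniquely mapped" proxy)
        _sam_line("PAIR4", 99, 4001, 5, "75M", 4093, 167),
        _sam_line("PAIR4", 147, 4093, 5, "75M", 4001, -167),
        # orphan without its mate in the file
        _sam_line("PAIR5", 99, 5001, 60, "75M", 5093, 167),
    ]
    p = tmp_path / "reads.sam"
    p.write_text(SAM_HEADER + "".join(lines))
    return p


def test_paired_alignments_extraction(sam_path):
    with pytest.warns(UserWarning, match="orphan"):
        fs = fragments_from_paired_alignments(sam_path, "S1", "INPUT")
    assert len(fs) == 1
    rec = fs.frame.iloc[0]
    assert (rec["chrom"], rec["start"], rec["end"]) == ("chr1", 1000, 1167)
    assert rec["barcode"] == "AAGGCTTA"
    drops = fs.report["dropped"]
    assert drops["short_insert"] == 1
    assert drops["not_proper_pair"] == 2
    assert drops["low_mapq"] == 2
    assert drops["orphan"] == 1


def test_paired_alignments_barcode_from_name(tmp_path):
    p = tmp_path / "named.sam"
    p.write_text(SAM_HEADER
                 + _sam_line("CCTTGGAA:r7", 99, 1001, 60, "75M", 1093, 167)
                 + _sam_line("CCTTGGAA:r7", 147, 1093, 60, "75M", 1001, -167))
    fs = fragments_from_paired_alignments(p, "S1", "IP",
                                          barcode_source="name")
    assert list(fs.frame["barcode"]) == ["CCTTGGAA"]


def test_alignment_round_trip_through_table(sam_path, tmp_path):
    with pytest.warns(UserWarning):
        fs = fragments_from_paired_alignments(sam_path, "S1", "INPUT")
    out = tmp_path / "frags.tsv"
    write_fragment_table(fs, out)
    back = read_fragment_table(out, "S1", "INPUT")
    pd.testing.assert_frame_equal(back.frame, fs.frame)


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------


def test_deduplicate_collapses_barcode_key():
    fs = make_fragment_set("S", "IP",
                           ["chr1"] * 3, [1000] * 3, [1167] * 3,
                           ["AAGG", "AAGG", "CCTT"])
    dd = deduplicate(fs)
    assert len(dd) == 2
    assert dd.dedup_applied
    assert dd.report["duplicates_removed"] == 1
    # first-encountered record retained
    assert list(dd.frame["barcode"]) == ["AAGG", "CCTT"]


def test_deduplicate_identity_and_idempotence(rng=np.random.default_rng(5)):
    n = 500
    fs = make_fragment_set(
        "S", "INPUT",
        np.where(rng.random(n) < 0.5, "chr1", "chr2"),
        rng.integers(0, 1000, n) * 10,
        rng.integers(0, 1000, n) * 10 + rng.integers(100, 221, n),
        rng.integers(0, 50, n).astype(str))
    once = deduplicate(fs)
    twice = deduplicate(once)
    pd.testing.assert_frame_equal(once.frame, twice.frame)
    assert twice.report["duplicates_removed"] == 0
    # empty set
    assert len(deduplicate(fs.with_frame(fs.frame.iloc[:0]))) == 0
    # all-distinct keys -> identity
    distinct = make_fragment_set("S", "INPUT", ["chr1"] * 3,
                                 [0, 10, 20], [200, 210, 220],
                                 ["a", "b", "c"])
    pd.testing.assert_frame_equal(deduplicate(distinct).frame, distinct.frame)


# ---------------------------------------------------------------------------
# size filter
# ---------------------------------------------------------------------------


def test_filter_size_range_boundaries():
    fs = fragments_of_lengths([99, 100, 220, 221])
    kept = filter_size_range(fs)
    assert sorted(kept.lengths) == [100, 220]


def test_filter_size_range_degenerate_and_errors():
    fs = fragments_of_lengths([166, 167, 168])
    assert list(filter_size_range(fs, 167, 167).lengths) == [167]
    assert len(filter_size_range(fs.with_frame(fs.frame.iloc[:0]))) == 0
    with pytest.raises(ValueError):
        filter_size_range(fs, 200, 100)
    # wide bounds are the identity
    wide = filter_size_range(fs, 1, 10**9)
    pd.testing.assert_frame_equal(wide.frame, fs.frame)


# ---------------------------------------------------------------------------
# window assignment
# ---------------------------------------------------------------------------


def test_midpoint_assignment_example(tiny_grid):
    # midpoint of [9995, 10162) is 10078 -> second 10-kb window
    fs = make_fragment_set("S", "IP", ["chr1"], [9995], [10162], ["x"])
    assert list(fragment_window_ids(fs, tiny_grid)) == [1]
    mapping = assign_to_windows(fs, tiny_grid)
    assert set(mapping) == {1} and list(mapping[1]) == [0]


def test_window_assignment_conservation(small_cohort, small_cfg):
    fs = prep(small_cohort.samples[0].ip_set)
    counts = window_counts(fs, small_cfg.grid)
    assert counts.sum() == len(fs)
    mapping = assign_to_windows(fs, small_cfg.grid)
    assert sum(len(v) for v in mapping.values()) == len(fs)


def test_window_assignment_unknown_chromosome(tiny_grid):
    fs = make_fragment_set("S", "IP", ["chrX"], [0], [167], ["x"])
    with pytest.raises(KeyError, match="chrX"):
        fragment_window_ids(fs, tiny_grid)


def test_window_grid_geometry():
    grid = WindowGrid(GenomeLayout(("chr1", "chr2"), (25_000, 10_000)), 10_000)
    assert grid.n_windows == 4
    assert grid.windows_per_chrom == (3, 1)
    # last window of chr1 is shorter
    assert grid.window_bounds(2) == ("chr1", 20_000, 25_000)
    assert grid.window_bounds(3) == ("chr2", 0, 10_000)
    assert grid.flat_id("chr2", 0) == 3
    tab = grid.windows_table()
    assert ((tab["end"] - tab["start"]) > 0).all()
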