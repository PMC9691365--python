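"""Interval model, BED I/O, center-merging, promoter and nearest-gene logic."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cafcall import (
    GeneAnnotation,
    GenomicInterval,
    RegionSet,
    classify_promoter,
    merge_by_center,
    nearest_gene,
    nearest_genes,
    overlaps,
    read_bed,
    write_bed,
)
from cafcall.intervals import BedParseError, classify_promoters, overlap_length


# ---------------------------------------------------------------------------
# oracles (quadratic brute force, independent of the implementation)
# ---------------------------------------------------------------------------

def merge_oracle(intervals, d):
    """Union-find over all pairs whose centers are within d on one chrom."""
    items = list(intervals)
    parent = list(range(len(items)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            a, b = items[i], items[j]
            if a.chrom == b.chrom and abs(a.center - b.center) <= d:
                parent[find(i)] = find(j)
    groups = {}
    for i, iv in enumerate(items):
        groups.setdefault(find(i), []).append(iv)
    merged = [
        (g[0].chrom, min(iv.start for iv in g), max(iv.end for iv in g))
        for g in groups.values()
    ]
    return sorted(merged)


def overlap_oracle(a, b):
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def promoter_oracle(region, genes, flank):
    for g in genes:
        win = GenomicInterval(g.chrom, max(0, g.tss - flank), g.tss + flank + 1)
        if overlap_oracle(region, win) >= 1:
            return "promoter"
    return "non_promoter"


def nearest_oracle(region, genes):
    cands = [g for g in genes if g.chrom == region.chrom]
    return min(
        cands, key=lambda g: (abs(g.tss - region.center), g.tss, g.gene_id)
    ).gene_id


def random_regions(rng, n, span=2000, chroms=("chr1", "chr2")):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        end = start + int(rng.integers(1, 400))
        out.append(GenomicInterval(str(rng.choice(chroms)), start, end))
    return out


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

def test_interval_invariants():
    iv = GenomicInterval("chr1", 100, 201)
    assert iv.center == 150 and len(iv) == 101
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 200, 100)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", -1, 100)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 0, 10, strand="x")


def test_regionset_sorts_and_deduplicates():
    a = GenomicInterval("chr2", 5, 10)
    b = GenomicInterval("chr1", 50, 60)
    rs = RegionSet([a, b, a])
    assert len(rs) == 2
    assert [iv.chrom for iv in rs] == ["chr1", "chr2"]


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def test_read_bed_field_mapping(tmp_path):
    p = tmp_path / "x.bed"
    p.write_text("chr1\t100\t200\tpk1\n")
    rs = read_bed(p)
    iv = rs[0]
    assert (iv.chrom, iv.start, iv.end, iv.name) == ("chr1", 100, 200, "pk1")


def test_read_bed_empty_file(tmp_path):
    p = tmp_path / "empty.bed"
    p.write_text("")
    assert len(read_bed(p)) == 0


@pytest.mark.parametrize(
    "line", ["chr1\t200\t100", "chr1\tabc\t100", "chr1\t100"]
)
def test_read_bed_malformed_names_line(tmp_path, line):
    p = tmp_path / "bad.bed"
    p.write_text("chr1\t1\t2\tok\n" + line + "\n")
    with pytest.raises(BedParseError, match=":2"):
        read_bed(p)


def test_bed4_roundtrip_byte_identical(tmp_path):
    content = "chr1\t10\t20\tA\nchr1\t30\t45\tB\nchr2\t5\t100\tC\n"
    src = tmp_path / "in.bed"
    src.write_text(content)
    dst = tmp_path / "out.bed"
    write_bed(read_bed(src), dst, columns=4)
    assert dst.read_text() == content


# ---------------------------------------------------------------------------
# merge_by_center
# ---------------------------------------------------------------------------

def test_merge_two_close_centers():
    rs = RegionSet([GenomicInterval("chr1", 50, 150), GenomicInterval("chr1", 200, 300)])
    out = merge_by_center(rs, 200)  # centers 100 and 250, distance 150
    assert len(out) == 1 and out[0].start == 50 and out[0].end == 300


def test_merge_chains_past_direct_distance():
    # centers 100, 290, 480: 100<->480 is 380 > 200, but the chain links them
    rs = RegionSet(
        [
            GenomicInterval("chr1", 50, 150),
            GenomicInterval("chr1", 240, 340),
            GenomicInterval("chr1", 430, 530),
        ]
    )
    out = merge_by_center(rs, 200)
    assert len(out) == 1
    assert (out[0].start, out[0].end) == (50, 530)
    assert merge_oracle(rs, 200) == [(iv.chrom, iv.start, iv.end) for iv in out]


def test_merge_singleton_identity():
    rs = RegionSet([GenomicInterval("chr1", 10, 20)])
    assert merge_by_center(rs, 200) == rs


def test_merge_matches_bruteforce_oracle():
    rng = np.random.default_rng(42)
    for _ in range(60):
        rs = RegionSet(random_regions(rng, int(rng.integers(1, 25))))
        d = int(rng.integers(0, 300))
        got = [(iv.chrom, iv.start, iv.end) for iv in merge_by_center(rs, d)]
        assert got == merge_oracle(rs, d)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(0, 1000), st.integers(1, 200)), min_size=1, max_size=15
    ),
    st.integers(0, 250),
)
def test_merge_idempotent_and_order_invariant(raw, d):
    ivs = [GenomicInterval("chr1", s, s + w) for s, w in raw]
    once = merge_by_center(RegionSet(ivs), d)
    assert merge_by_center(once, d) == once
    shuffled = RegionSet(list(reversed(ivs)))
    assert merge_by_center(shuffled, d) == once
    # every input region is contained in its group's merged span (merged
    # spans of distinct groups may themselves overlap, so >= 1, not == 1)
    for iv in ivs:
        containing = [m for m in once if m.start <= iv.start and iv.end <= m.end]
        assert len(containing) >= 1


def test_merge_d_zero_groups_identical_centers_only():
    rs = RegionSet(
        [
            GenomicInterval("chr1", 100, 200),  # center 150
            GenomicInterval("chr1", 120, 180),  # center 150
            GenomicInterval("chr1", 151, 251),  # center 201
        ]
    )
    out = merge_by_center(rs, 0)
    assert [(iv.start, iv.end) for iv in out] == [(100, 200), (151, 251)]


# ---------------------------------------------------------------------------
# overlaps / promoter / nearest gene
# ---------------------------------------------------------------------------

def test_overlaps_boundary_cases():
    a = GenomicInterval("chr1", 100, 200)
    assert overlaps(a, GenomicInterval("chr1", 199, 300))       # 1 bp
    assert not overlaps(a, GenomicInterval("chr1", 200, 300))   # abutting
    assert not overlaps(a, GenomicInterval("chr2", 100, 200))   # other chrom
    assert not overlaps(a, GenomicInterval("chr1", 150, 300), min_bp=51)
    assert overlaps(a, GenomicInterval("chr1", 150, 300), min_bp=50)


def test_overlap_length_matches_oracle_on_random_pairs():
    rng = np.random.default_rng(7)
    pairs = zip(random_regions(rng, 300), random_regions(rng, 300))
    for a, b in pairs:
        assert overlap_length(a, b) == overlap_oracle(a, b)


def test_promoter_classification_examples():
    genes = [GeneAnnotation("g1", "chr1", 1000, "+")]
    assert classify_promoter(GenomicInterval("chr1", 500, 600), genes) == "promoter"
    assert (
        classify_promoter(GenomicInterval("chr1", 5000, 5100), genes)
        == "non_promoter"
    )
    # window is [tss-flank, tss+flank+1): position 2000 still overlaps
    assert classify_promoter(GenomicInterval("chr1", 2000, 2100), genes) == "promoter"
    assert (
        classify_promoter(GenomicInterval("chr1", 2001, 2100), genes)
        == "non_promoter"
    )


def test_promoter_matches_naive_scan_on_random_regions():
    rng = np.random.default_rng(11)
    genes = [
        GeneAnnotation(f"g{i}", str(rng.choice(["chr1", "chr2"])),
                       int(rng.integers(0, 5000)), "+")
        for i in range(30)
    ]
    regions = RegionSet(random_regions(rng, 400, span=5000))
    flank = 300
    got = classify_promoters(regions, genes, flank)
    expected = [promoter_oracle(iv, genes, flank) for iv in regions]
    assert got == expected


def test_nearest_gene_examples_and_tiebreak():
    genes = [
        GeneAnnotation("far", "chr1", 3000, "+"),
        GeneAnnotation("near", "chr1", 1000, "+"),
    ]
    region = GenomicInterval("chr1", 1400, 1601)  # center 1500
    assert nearest_gene(region, genes) == "near"
    tie = [
        GeneAnnotation("b", "chr1", 2000, "+"),
        GeneAnnotation("a", "chr1", 1000, "+"),
    ]
    # equidistant: smaller TSS wins
    assert nearest_gene(region, tie) == "a"
    same_tss = [
        GeneAnnotation("zz", "chr1", 1000, "+"),
        GeneAnnotation("aa", "chr1", 1000, "+"),
    ]
    assert nearest_gene(region, same_tss) == "aa"
    with pytest.raises(ValueError):
        nearest_gene(region, [])


def test_nearest_genes_vectorized_matches_scalar_oracle():
    rng = np.random.default_rng(23)
    genes = [
        GeneAnnotation(f"g{i:03d}", str(rng.choice(["chr1", "chr2"])),
                       int(rng.integers(0, 10000)), "+")
        for i in range(50)
    ]
    regions = RegionSet(random_regions(rng, 300, span=10000))
    assert nearest_genes(regions, genes) == [nearest_oracle(iv, genes) for iv in regions]
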