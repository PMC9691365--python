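"""Genomic-interval data model and region arithmetic.

Coordinates are 0-based, half-open everywhere (BED native).  The two
operations that carry method-specific semantics live here:

* :func:`merge_by_center` — HOMER ``mergePeaks``-style merging in which two
  peaks belong together when their *centers* are within a distance ``d``
  (default 200 bp in the pipeline), taken to transitive closure, with the
  merged span being the union span of the chained group.
* promoter classification against TSS ± 1 kb and nearest-gene assignment by
  TSS-to-center distance, which anchor all enhancer→gene annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "GeneAnnotation",
    "RegionSet",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "merge_by_center",
    "overlaps",
    "overlap_length",
    "classify_promoter",
    "nearest_gene",
]


class BedParseError(ValueError):
    """Malformed BED input; message names the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of +,-,. got {self.strand!r}")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene reduced to its transcription start site."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be >= 0")


class RegionSet:
    """Ordered, de-duplicated collection of :class:`GenomicInterval`.

    Always sorted by ``(chrom, start, end)``; duplicate records (same chrom,
    start, end, name) are collapsed.  ``label`` carries provenance such as a
    sample id and histone mark.
    """

    def __init__(
        self, intervals: Iterable[GenomicInterval] = (), label: str = ""
    ) -> None:
        seen: set[tuple] = set()
        unique = []
        for iv in intervals:
            key = (iv.chrom, iv.start, iv.end, iv.name)
            if key not in seen:
                seen.add(key)
                unique.append(iv)
        self._intervals: list[GenomicInterval] = sorted(
            unique, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        self.label = label

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self._intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return [
            (iv.chrom, iv.start, iv.end) for iv in self
        ] == [(iv.chrom, iv.start, iv.end) for iv in other]

    def __repr__(self) -> str:
        lab = f" label={self.label!r}" if self.label else ""
        return f"<RegionSet n={len(self)}{lab}>"

    @property
    def region_ids(self) -> list[str]:
        return [iv.region_id for iv in self._intervals]

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self._intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self],
                "start": [iv.start for iv in self],
                "end": [iv.end for iv in self],
                "name": [iv.name or "." for iv in self],
                "score": [0.0 if iv.score is None else iv.score for iv in self],
                "strand": [iv.strand for iv in self],
            }
        )


# ---------------------------------------------------------------------------
# BED and annotation I/O
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, label: str = "") -> RegionSet:
    """Read BED3/BED4/BED6 into a sorted :class:`RegionSet`.

    BED's native 0-based half-open coordinates are preserved unchanged.
    Lines beginning with ``track``, ``browser`` or ``#`` are skipped.
    """
    path = Path(path)
    intervals = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if end <= start or start < 0:
                raise BedParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            intervals.append(
                GenomicInterval(chrom, start, end, name, score, strand)
            )
    return RegionSet(intervals, label=label or path.stem)


def write_bed(regions: RegionSet, path: str | Path, columns: int = 4) -> None:
    """Write BED with 3, 4 or 6 columns (canonical tab-separated)."""
    if columns not in (3, 4, 6):
        raise ValueError("columns must be 3, 4 or 6")
    with Path(path).open("w") as fh:
        for i, iv in enumerate(regions):
            row = [iv.chrom, str(iv.start), str(iv.end)]
            if columns >= 4:
                row.append(iv.name if iv.name is not None else f"region_{i}")
            if columns == 6:
                row.append("0" if iv.score is None else f"{iv.score:g}")
                row.append(iv.strand)
            fh.write("\t".join(row) + "\n")


def read_gene_table(path: str | Path) -> list[GeneAnnotation]:
    """Read a gene annotation TSV with header ``gene_id chrom tss strand``.

    The ``tss`` column is 0-based.  Tables exported from 1-based sources
    must be shifted by the exporter; this reader does not guess.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    return [
        GeneAnnotation(str(r.gene_id), str(r.chrom), int(r.tss), str(r.strand))
        for r in df.itertuples()
    ]


def write_gene_table(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "tss": [g.tss for g in genes],
            "strand": [g.strand for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Region arithmetic
# ---------------------------------------------------------------------------

def merge_by_center(regions: RegionSet, d: int = 200) -> RegionSet:
    """Merge regions whose centers lie within ``d`` bp, transitively.

    Within one chromosome, any two regions with center distance <= d are in
    the same merged group; chains are allowed, so the two ends of a group
    may be farther apart than d.  Each merged region spans
    ``min(start)..max(end)`` of its group.  On a line, transitive closure of
    the center-distance relation is exactly chaining of center-sorted
    neighbours, which is what is done here; the result is idempotent because
    every merged center stays within the span of its members' centers.
    """
    if d < 0:
        raise ValueError("merge distance d must be >= 0")
    merged: list[GenomicInterval] = []
    for chrom, ivs in regions.by_chrom().items():
        ivs = sorted(ivs, key=lambda iv: (iv.center, iv.start, iv.end))
        group_start, group_end = ivs[0].start, ivs[0].end
        prev_center = ivs[0].center
        for iv in ivs[1:]:
            if iv.center - prev_center <= d:
                group_start = min(group_start, iv.start)
                group_end = max(group_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, group_start, group_end))
                group_start, group_end = iv.start, iv.end
            prev_center = iv.center
        merged.append(GenomicInterval(chrom, group_start, group_end))
    return RegionSet(merged, label=regions.label)


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlaps(a: GenomicInterval, b: GenomicInterval, min_bp: int = 1) -> bool:
    """True iff the two half-open intervals share at least ``min_bp`` bases."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    return overlap_length(a, b) >= min_bp


def _tss_arrays(genes: Sequence[GeneAnnotation]) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[int]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g.tss)
    return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in by_chrom.items()}


def classify_promoter(
    region: GenomicInterval,
    genes: Sequence[GeneAnnotation],
    flank: int = 1000,
) -> str:
    """Classify a region as ``promoter`` or ``non_promoter``.

    A region is a promoter iff it overlaps ``[tss - flank, tss + flank + 1)``
    of any gene by >= 1 bp; the window is strand-symmetric.
    """
    if not genes:
        raise ValueError("gene annotation must be non-empty")
    tss = _tss_arrays(genes).get(region.chrom)
    if tss is None:
        return "non_promoter"
    # overlap iff tss - flank < region.end  and  tss + flank + 1 > region.start
    lo = np.searchsorted(tss, region.start - flank, side="left")
    hi = np.searchsorted(tss, region.end + flank - 1, side="right")
    return "promoter" if hi > lo else "non_promoter"


def classify_promoters(
    regions: RegionSet, genes: Sequence[GeneAnnotation], flank: int = 1000
) -> list[str]:
    """Vectorized promoter classification for a whole RegionSet."""
    if not genes:
        raise ValueError("gene annotation must be non-empty")
    tss_by_chrom = _tss_arrays(genes)
    labels = []
    for iv in regions:
        tss = tss_by_chrom.get(iv.chrom)
        if tss is None:
            labels.append("non_promoter")
            continue
        lo = np.searchsorted(tss, iv.start - flank, side="left")
        hi = np.searchsorted(tss, iv.end + flank - 1, side="right")
        labels.append("promoter" if hi > lo else "non_promoter")
    return labels


def nearest_gene(
    region: GenomicInterval, genes: Sequence[GeneAnnotation]
) -> str:
    """Gene whose TSS is closest to the region center, same chromosome.

    Ties are broken by the smaller TSS coordinate, then lexicographically
    smaller gene_id, so the assignment is deterministic.
    """
    if not genes:
        raise ValueError("gene annotation must be non-empty")
    candidates = [g for g in genes if g.chrom == region.chrom]
    if not candidates:
        raise ValueError(f"no gene on chromosome {region.chrom!r}")
    center = region.center
    best = min(candidates, key=lambda g: (abs(g.tss - center), g.tss, g.gene_id))
    return best.gene_id


def nearest_genes(
    regions: RegionSet, genes: Sequence[GeneAnnotation]
) -> list[str]:
    """Nearest-gene assignment for a whole RegionSet (sorted-TSS search)."""
    if not genes:
        raise ValueError("gene annotation must be non-empty")
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    # sort genes by (tss, gene_id) so equal-distance ties resolve the same
    # way as the scalar routine
    sorted_by_chrom = {
        c: sorted(v, key=lambda g: (g.tss, g.gene_id)) for c, v in by_chrom.items()
    }
    tss_by_chrom = {
        c: np.asarray([g.tss for g in v], dtype=np.int64)
        for c, v in sorted_by_chrom.items()
    }
    out = []
    for iv in regions:
        glist = sorted_by_chrom.get(iv.chrom)
        if glist is None:
            raise ValueError(f"no gene on chromosome {iv.chrom!r}")
        tss = tss_by_chrom[iv.chrom]
        c = iv.center
        j = int(np.searchsorted(tss, c))
        cand_idx = [i for i in (j - 1, j, j + 1) if 0 <= i < len(glist)]
        # widen to cover runs of equal TSS around the insertion point
        lo = min(cand_idx)
        while lo > 0 and tss[lo - 1] == tss[lo]:
            lo -= 1
        hi = max(cand_idx)
        while hi + 1 < len(glist) and tss[hi + 1] == tss[hi]:
            hi += 1
        best = min(
            glist[lo : hi + 1],
            key=lambda g: (abs(g.tss - c), g.tss, g.gene_id),
        )
        out.append(best.gene_id)
    return out
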