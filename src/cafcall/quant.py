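"""Fragment counting, per-million normalization and paired fold changes.

A fragment is assigned to a region iff its midpoint lies within the region
(half-open).  Midpoint assignment, rather than any-overlap, keeps one
fragment from inflating two abutting regions.  Counts are normalized to
fragments per million total unique fragments of the sample (RPM), with a
one-fragment pseudocount added before scaling so every downstream fold
change is finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, RegionSet, read_bed

__all__ = [
    "FragmentSet",
    "EnrichmentMatrix",
    "PairedDesign",
    "count_in_regions",
    "read_fragment_table",
    "rpm_normalize",
    "build_enrichment_matrix",
    "paired_fold_change",
    "read_sample_metadata",
]


@dataclass
class FragmentSet:
    """Aligned-fragment placements of one sample for one histone mark.

    ``fragments`` is either a :class:`RegionSet` or a plain DataFrame with
    ``chrom``/``start``/``end`` columns — the latter is the fast path for
    the millions of rows a real sample carries (only fragment midpoints are
    ever used downstream).
    """

    sample_id: str
    mark: str
    fragments: RegionSet | pd.DataFrame
    total_unique: int

    def __post_init__(self) -> None:
        if self.total_unique <= 0:
            raise ValueError("total_unique must be > 0")
        if self.total_unique < len(self.fragments):
            raise ValueError(
                "total_unique cannot be smaller than the fragments supplied"
            )

    def midpoints_by_chrom(self) -> dict[str, np.ndarray]:
        """Sorted fragment midpoints per chromosome."""
        out: dict[str, np.ndarray] = {}
        if isinstance(self.fragments, pd.DataFrame):
            df = self.fragments
            mids = ((df["start"].to_numpy(np.int64) + df["end"].to_numpy(np.int64)) // 2)
            for chrom, idx in df.groupby("chrom", sort=True).indices.items():
                out[str(chrom)] = np.sort(mids[idx])
        else:
            for chrom, ivs in self.fragments.by_chrom().items():
                out[chrom] = np.sort(
                    np.array([(iv.start + iv.end) // 2 for iv in ivs], dtype=np.int64)
                )
        return out


def read_fragment_table(path: str | Path) -> pd.DataFrame:
    """Fast BED3 reader for fragment files (C parser, no per-row objects)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
        comment="#",
    )
    if (df["end"] <= df["start"]).any():
        bad = int((df["end"] <= df["start"]).idxmax()) + 1
        raise ValueError(f"{path}: invalid interval at data line {bad}")
    return df


@dataclass
class PairedDesign:
    """Patient -> (NF sample, CAF sample) mapping.

    Fold changes are always oriented CAF / paired NF.
    """

    pairs: dict[str, tuple[str, str]]  # patient -> (nf_id, caf_id)

    def __post_init__(self) -> None:
        ids = [s for pair in self.pairs.values() for s in pair]
        if len(ids) != len(set(ids)):
            raise ValueError("sample ids in the design must be distinct")

    @property
    def patients(self) -> list[str]:
        return list(self.pairs)

    @property
    def n_patients(self) -> int:
        return len(self.pairs)

    @property
    def nf_samples(self) -> list[str]:
        return [nf for nf, _ in self.pairs.values()]

    @property
    def caf_samples(self) -> list[str]:
        return [caf for _, caf in self.pairs.values()]

    @property
    def all_samples(self) -> list[str]:
        return self.nf_samples + self.caf_samples

    def swapped(self) -> "PairedDesign":
        """Design with NF and CAF labels exchanged (for symmetry checks)."""
        return PairedDesign({p: (caf, nf) for p, (nf, caf) in self.pairs.items()})

    @classmethod
    def from_metadata(cls, meta: pd.DataFrame) -> "PairedDesign":
        """Build from a sample metadata table with patient/condition columns."""
        pairs = {}
        for patient, grp in meta.groupby("patient", sort=True):
            nf = grp.loc[grp["condition"] == "NF", "sample_id"]
            caf = grp.loc[grp["condition"] == "CAF", "sample_id"]
            if len(nf) != 1 or len(caf) != 1:
                raise ValueError(
                    f"patient {patient!r} needs exactly one NF and one CAF sample"
                )
            pairs[str(patient)] = (str(nf.iloc[0]), str(caf.iloc[0]))
        return cls(pairs)


@dataclass
class EnrichmentMatrix:
    """Regions x samples matrix of per-million-normalized fragment counts."""

    regions: RegionSet
    values: pd.DataFrame  # index = region ids, columns = sample ids
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if list(self.values.index) != self.regions.region_ids:
            raise ValueError("matrix rows must match the RegionSet order")
        if self.values.columns.duplicated().any():
            raise ValueError("sample columns must be unique")
        if (self.values.values < 0).any():
            raise ValueError("RPM values must be >= 0")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="region")


def count_in_regions(fragments: FragmentSet | RegionSet, regions: RegionSet) -> np.ndarray:
    """Count fragments whose midpoint falls in each region.

    Regions may overlap one another; a fragment whose midpoint lies in two
    regions is counted once in each (at most once per region).
    """
    if isinstance(fragments, FragmentSet):
        mids_by_chrom = fragments.midpoints_by_chrom()
    else:
        mids_by_chrom = {
            chrom: np.sort(
                np.array([(iv.start + iv.end) // 2 for iv in ivs], dtype=np.int64)
            )
            for chrom, ivs in fragments.by_chrom().items()
        }
    counts = np.zeros(len(regions), dtype=np.int64)
    for i, region in enumerate(regions):
        mids = mids_by_chrom.get(region.chrom)
        if mids is None:
            continue
        lo = np.searchsorted(mids, region.start, side="left")
        hi = np.searchsorted(mids, region.end, side="left")
        counts[i] = hi - lo
    return counts


def rpm_normalize(
    counts: np.ndarray, total_unique: int, pseudocount: float = 1.0
) -> np.ndarray:
    """``(count + pseudocount) * 1e6 / total_unique`` per region."""
    if total_unique <= 0:
        raise ValueError("total_unique must be > 0")
    return (np.asarray(counts, dtype=float) + pseudocount) * 1e6 / total_unique


def build_enrichment_matrix(
    fragment_sets: Sequence[FragmentSet],
    regions: RegionSet,
    pseudocount: float = 1.0,
) -> EnrichmentMatrix:
    """Quantify several samples on one region set into an RPM matrix."""
    ids = [fs.sample_id for fs in fragment_sets]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sample ids among fragment sets")
    cols = {
        fs.sample_id: rpm_normalize(
            count_in_regions(fs, regions), fs.total_unique, pseudocount
        )
        for fs in fragment_sets
    }
    values = pd.DataFrame(cols, index=regions.region_ids)
    return EnrichmentMatrix(regions=regions, values=values, pseudocount=pseudocount)


def paired_fold_change(
    matrix: EnrichmentMatrix, design: PairedDesign
) -> pd.DataFrame:
    """Fold change (CAF / paired NF) of enrichment per region per patient."""
    missing = [s for s in design.all_samples if s not in matrix.values.columns]
    if missing:
        raise ValueError(f"samples missing from matrix: {missing}")
    fc = {
        patient: matrix.values[caf] / matrix.values[nf]
        for patient, (nf, caf) in design.pairs.items()
    }
    return pd.DataFrame(fc, index=matrix.values.index)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV.

    Columns: sample_id, patient, condition (NF|CAF), mark, total_unique,
    path (fragment BED, relative to the metadata file's directory).
    """
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient": str})
    required = {"sample_id", "patient", "condition", "mark", "total_unique", "path"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return meta


def load_fragment_sets(
    meta: pd.DataFrame, base_dir: str | Path, mark: str | None = None
) -> dict[str, FragmentSet]:
    """Load fragment BEDs referenced by a metadata table, keyed by sample."""
    base = Path(base_dir)
    out = {}
    rows = meta if mark is None else meta[meta["mark"] == mark]
    for r in rows.itertuples():
        frags = read_fragment_table(base / r.path)
        out[str(r.sample_id)] = FragmentSet(
            sample_id=str(r.sample_id),
            mark=str(r.mark),
            fragments=frags,
            total_unique=int(r.total_unique),
        )
    return out
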