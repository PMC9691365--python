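"""Consensus differential enhancer calling across a paired NF/CAF cohort.

The core inference: per-patient changed H3K27ac peaks, TOP-k most-changed
regions by summed fold change, active-enhancer definition (H3K27ac peak
overlapping an H3K4me1 peak by >= 1 bp in the same sample), and the
paired-consensus call — a region is CAF-activated when its H3K27ac
enrichment is >= fc_up-fold higher in CAF than in the paired NF in at least
``min_pairs`` patients, and CAF-repressed symmetrically at <= fc_down.
With six pairs the default ``min_pairs = 4`` encodes "in more than 3 pairs"
and keeps the two sets provably disjoint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (
    GeneAnnotation,
    GenomicInterval,
    RegionSet,
    classify_promoters,
    merge_by_center,
    nearest_genes,
    overlaps,
    write_bed,
)
from .quant import (
    EnrichmentMatrix,
    FragmentSet,
    PairedDesign,
    build_enrichment_matrix,
    paired_fold_change,
)

__all__ = [
    "ConsensusParams",
    "EnhancerCallResult",
    "per_patient_changed_peaks",
    "top_changed_regions",
    "active_enhancers",
    "consensus_masks",
    "call_consensus_enhancers",
    "expression_association",
]


def default_min_pairs(n_patients: int) -> int:
    """Strict majority: floor(n/2) + 1 (4 of 6 encodes "> 3 pairs")."""
    return n_patients // 2 + 1


@dataclass(frozen=True)
class ConsensusParams:
    """Thresholds of the consensus caller.

    fc_up / fc_down are fold-change cut-offs (CAF / paired NF) for the
    activated and repressed directions; min_pairs is the minimum number of
    patients in which the cut-off must hold (None = strict majority of the
    design); merge_d is the center-distance used when peak sets are merged;
    min_overlap_bp is the H3K4me1 overlap needed for a peak to count as an
    active enhancer; top_k is the size of the most-changed-region lists.
    """

    fc_up: float = 2.0
    fc_down: float = 0.5
    min_pairs: int | None = None
    merge_d: int = 200
    min_overlap_bp: int = 1
    top_k: int = 2000
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.fc_up <= 1:
            raise ValueError("fc_up must be > 1")
        if not 0 < self.fc_down < 1:
            raise ValueError("fc_down must be in (0, 1)")

    def resolve_min_pairs(self, n_patients: int) -> int:
        mp = self.min_pairs if self.min_pairs is not None else default_min_pairs(n_patients)
        if not 1 <= mp <= n_patients:
            raise ValueError(
                f"min_pairs must be in [1, {n_patients}], got {mp}"
            )
        return mp


@dataclass
class EnhancerCallResult:
    """Output of the consensus caller with full provenance."""

    all_enhancers: RegionSet
    activated: RegionSet
    repressed: RegionSet
    fc_table: pd.DataFrame          # regions x patients
    pass_up: pd.DataFrame           # bool, regions x patients
    pass_down: pd.DataFrame         # bool, regions x patients
    matrix: EnrichmentMatrix
    params: ConsensusParams
    min_pairs_used: int

    def __post_init__(self) -> None:
        act = set(self.activated.region_ids)
        rep = set(self.repressed.region_ids)
        if act & rep:
            raise ValueError("activated and repressed sets must be disjoint")
        union = set(self.all_enhancers.region_ids)
        if not (act <= union and rep <= union):
            raise ValueError("called sets must be subsets of the union")

    def write(self, out_dir: str | Path) -> None:
        """Write BEDs (score = passing patients), FC table and manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        n_up = self.pass_up.sum(axis=1)
        n_down = self.pass_down.sum(axis=1)

        def _scored(rs: RegionSet, score: pd.Series) -> RegionSet:
            return RegionSet(
                [
                    GenomicInterval(
                        iv.chrom, iv.start, iv.end, iv.region_id,
                        float(score[iv.region_id]),
                    )
                    for iv in rs
                ],
                label=rs.label,
            )

        write_bed(self.all_enhancers, out / "all_enhancers.bed", columns=4)
        write_bed(_scored(self.activated, n_up), out / "caf_activated.bed", columns=6)
        write_bed(_scored(self.repressed, n_down), out / "caf_repressed.bed", columns=6)
        self.fc_table.to_csv(out / "fold_change.tsv", sep="\t", index_label="region")
        manifest = {
            "n_all_enhancers": len(self.all_enhancers),
            "n_activated": len(self.activated),
            "n_repressed": len(self.repressed),
            "min_pairs_used": self.min_pairs_used,
            "params": asdict(self.params),
        }
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def per_patient_changed_peaks(
    nf_peaks: RegionSet,
    caf_peaks: RegionSet,
    nf_fragments: FragmentSet,
    caf_fragments: FragmentSet,
    params: ConsensusParams = ConsensusParams(),
) -> tuple[RegionSet, RegionSet]:
    """Changed H3K27ac peaks of one patient.

    NF and CAF peak sets are center-merged into one set of candidate
    regions, both samples are quantified on them (RPM), and regions with
    CAF/NF fold change >= fc_up (increased) or <= fc_down (decreased) are
    returned.  The two outputs are disjoint by construction.
    """
    combined = RegionSet(list(nf_peaks) + list(caf_peaks))
    merged = merge_by_center(combined, params.merge_d)
    matrix = build_enrichment_matrix(
        [nf_fragments, caf_fragments], merged, params.pseudocount
    )
    fc = matrix.values[caf_fragments.sample_id] / matrix.values[nf_fragments.sample_id]
    increased = RegionSet(
        [iv for iv, f in zip(merged, fc) if f >= params.fc_up], label="increased"
    )
    decreased = RegionSet(
        [iv for iv, f in zip(merged, fc) if f <= params.fc_down], label="decreased"
    )
    return increased, decreased


def top_changed_regions(
    matrix: EnrichmentMatrix,
    design: PairedDesign,
    genes: Sequence[GeneAnnotation],
    k: int = 2000,
    stratum: str = "non_promoter",
    flank: int = 1000,
) -> RegionSet:
    """TOP-k regions of a stratum by summed per-patient fold change.

    Regions are split into promoter / non-promoter (TSS +- flank), the per
    patient CAF/NF fold changes are summed, and the k highest-ranked regions
    of the requested stratum are returned (ties broken by chrom, start).
    """
    if stratum not in ("promoter", "non_promoter"):
        raise ValueError("stratum must be 'promoter' or 'non_promoter'")
    labels = classify_promoters(matrix.regions, genes, flank)
    fc = paired_fold_change(matrix, design)
    fc_sum = fc.sum(axis=1)
    in_stratum = [iv for iv, lab in zip(matrix.regions, labels) if lab == stratum]
    if k > len(in_stratum):
        raise ValueError(
            f"k={k} exceeds stratum size {len(in_stratum)} for {stratum!r}"
        )
    ranked = sorted(
        in_stratum,
        key=lambda iv: (-fc_sum[iv.region_id], iv.chrom, iv.start),
    )
    return RegionSet(ranked[:k], label=f"top{k}_{stratum}")


def active_enhancers(
    h3k27ac_peaks: RegionSet,
    h3k4me1_peaks: RegionSet,
    min_overlap_bp: int = 1,
) -> RegionSet:
    """H3K27ac peaks overlapping an H3K4me1 peak of the same sample.

    The overlap requirement defaults to 1 bp; retained peaks are the
    sample's active enhancers.
    """
    k4_by_chrom = h3k4me1_peaks.by_chrom()
    kept = []
    for chrom, peaks in h3k27ac_peaks.by_chrom().items():
        k4s = k4_by_chrom.get(chrom)
        if not k4s:
            continue
        ks = np.array([iv.start for iv in k4s], dtype=np.int64)
        ke = np.array([iv.end for iv in k4s], dtype=np.int64)
        ps = np.array([iv.start for iv in peaks], dtype=np.int64)
        pe = np.array([iv.end for iv in peaks], dtype=np.int64)
        ov = np.minimum(pe[:, None], ke[None, :]) - np.maximum(ps[:, None], ks[None, :])
        keep = (ov >= min_overlap_bp).any(axis=1)
        kept.extend(iv for iv, k in zip(peaks, keep) if k)
    return RegionSet(kept, label=f"{h3k27ac_peaks.label}:active")


def consensus_masks(
    matrix: EnrichmentMatrix,
    design: PairedDesign,
    params: ConsensusParams = ConsensusParams(),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.Series, pd.Series, int]:
    """Threshold an enrichment matrix into consensus activation calls.

    Returns (fc table, pass_up, pass_down, activated mask, repressed mask,
    min_pairs used).  Split out of :func:`call_consensus_enhancers` so the
    thresholding stage can be applied to any matrix directly.
    """
    min_pairs = params.resolve_min_pairs(design.n_patients)
    fc = paired_fold_change(matrix, design)
    pass_up = fc >= params.fc_up
    pass_down = fc <= params.fc_down
    act_mask = pass_up.sum(axis=1) >= min_pairs
    rep_mask = pass_down.sum(axis=1) >= min_pairs
    both = act_mask & rep_mask
    if both.any():
        raise ValueError(
            "regions qualified as both activated and repressed; "
            "min_pairs must exceed n_patients/2 to preclude this"
        )
    return fc, pass_up, pass_down, act_mask, rep_mask, min_pairs


def call_consensus_enhancers(
    active_sets: Mapping[str, RegionSet],
    fragment_sets: Mapping[str, FragmentSet],
    design: PairedDesign,
    params: ConsensusParams = ConsensusParams(),
) -> EnhancerCallResult:
    """Paired-consensus CAF-activated / CAF-repressed enhancer call.

    1. the union region set is the center-merge of all samples' active
       enhancers concatenated;
    2. H3K27ac fragments of every sample are re-counted on the union (RPM);
    3. fold change CAF/NF per patient;
    4. activated = FC >= fc_up in >= min_pairs patients, repressed =
       FC <= fc_down in >= min_pairs patients.
    """
    if design.n_patients < 2:
        raise ValueError("need at least 2 patients")
    missing = [s for s in design.all_samples if s not in active_sets]
    if missing:
        raise ValueError(f"active-enhancer sets missing for samples: {missing}")
    missing = [s for s in design.all_samples if s not in fragment_sets]
    if missing:
        raise ValueError(f"fragment sets missing for samples: {missing}")

    union = merge_by_center(
        RegionSet(
            [iv for s in design.all_samples for iv in active_sets[s]],
            label="all_enhancers",
        ),
        params.merge_d,
    )
    matrix = build_enrichment_matrix(
        [fragment_sets[s] for s in design.all_samples], union, params.pseudocount
    )
    fc, pass_up, pass_down, act_mask, rep_mask, min_pairs = consensus_masks(
        matrix, design, params
    )
    activated = RegionSet(
        [iv for iv, m in zip(union, act_mask) if m], label="caf_activated"
    )
    repressed = RegionSet(
        [iv for iv, m in zip(union, rep_mask) if m], label="caf_repressed"
    )
    return EnhancerCallResult(
        all_enhancers=union,
        activated=activated,
        repressed=repressed,
        fc_table=fc,
        pass_up=pass_up,
        pass_down=pass_down,
        matrix=matrix,
        params=params,
        min_pairs_used=min_pairs,
    )


def expression_association(
    result: EnhancerCallResult,
    genes: Sequence[GeneAnnotation],
    expr: pd.DataFrame,
    design: PairedDesign,
    rng: np.random.Generator | None = None,
    eps: float = 0.1,
) -> pd.DataFrame:
    """Do genes near activated enhancers go up with activation, per patient?

    For each patient the log2 expression fold change (CAF/NF, pseudocount
    eps) of the nearest genes of activated enhancers is compared with that
    of the nearest genes of an equally sized random draw from the remaining
    (non-activated) union enhancers, by a one-sided Wilcoxon rank-sum test
    (the two gene sets are unpaired).  Returns one row per patient with the
    p-value and the median log2-FC difference (effect).
    """
    if not genes:
        raise ValueError("gene annotation must be non-empty")
    if len(result.activated) == 0:
        raise ValueError("no activated enhancers to associate")
    rng = rng if rng is not None else np.random.default_rng(0)

    act_genes = sorted(set(nearest_genes(result.activated, genes)))
    activated_ids = set(result.activated.region_ids)
    background = RegionSet(
        [iv for iv in result.all_enhancers if iv.region_id not in activated_ids]
    )
    if len(background) == 0:
        raise ValueError("no non-activated enhancers available as background")
    idx = rng.choice(len(background), size=min(len(result.activated), len(background)), replace=False)
    control = RegionSet([background[int(i)] for i in sorted(idx)])
    ctrl_genes = sorted(set(nearest_genes(control, genes)))

    act_genes = [g for g in act_genes if g in expr.index]
    ctrl_genes = [g for g in ctrl_genes if g in expr.index]
    if len(act_genes) < 2 or len(ctrl_genes) < 2:
        raise ValueError("too few mapped genes for an association test")

    rows = {}
    for patient, (nf, caf) in design.pairs.items():
        lfc = np.log2((expr[caf] + eps) / (expr[nf] + eps))
        a = lfc.loc[act_genes].to_numpy()
        c = lfc.loc[ctrl_genes].to_numpy()
        stat, p = stats.mannwhitneyu(a, c, alternative="greater")
        rows[patient] = {
            "p_value": float(p),
            "effect": float(np.median(a) - np.median(c)),
            "n_activated_genes": len(a),
            "n_control_genes": len(c),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
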