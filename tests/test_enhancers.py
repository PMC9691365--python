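"""Per-patient differential peaks, TOP-k ranking, active enhancers and the
paired consensus caller."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cafcall import (
    ConsensusParams,
    EnrichmentMatrix,
    FragmentSet,
    GeneAnnotation,
    GenomicInterval,
    PairedDesign,
    RegionSet,
    active_enhancers,
    call_consensus_enhancers,
    consensus_masks,
    expression_association,
    per_patient_changed_peaks,
    top_changed_regions,
)
from cafcall.enhancers import default_min_pairs


def matrix_from_values(values: pd.DataFrame) -> EnrichmentMatrix:
    regions = RegionSet(
        [GenomicInterval("chr1", i * 1000, i * 1000 + 500) for i in range(len(values))]
    )
    values = values.set_axis(regions.region_ids, axis=0)
    return EnrichmentMatrix(regions=regions, values=values)


def six_pair_design():
    return PairedDesign({f"P{i}": (f"nf{i}", f"caf{i}") for i in range(1, 7)})


def matrix_with_fc(fc_rows):
    """One region per row; NF columns all 1.0, CAF columns = the FC vector."""
    design = six_pair_design()
    data = {}
    for i, (nf, caf) in enumerate(design.pairs.values(), start=1):
        data[nf] = [1.0] * len(fc_rows)
        data[caf] = [row[i - 1] for row in fc_rows]
    return matrix_from_values(pd.DataFrame(data)), design


# ---------------------------------------------------------------------------
# params
# ---------------------------------------------------------------------------

def test_default_min_pairs_is_strict_majority():
    assert default_min_pairs(6) == 4
    assert default_min_pairs(7) == 4
    assert default_min_pairs(2) == 2


def test_params_validation():
    with pytest.raises(ValueError):
        ConsensusParams(fc_up=1.0)
    with pytest.raises(ValueError):
        ConsensusParams(fc_down=1.5)


# ---------------------------------------------------------------------------
# per-patient changed peaks
# ---------------------------------------------------------------------------

def _fragments(intervals, sample, total):
    return FragmentSet(sample, "H3K27ac", RegionSet(intervals), total)


def test_per_patient_changed_peaks_directions():
    peak = GenomicInterval("chr1", 1000, 2000)
    nf_peaks = RegionSet([peak])
    caf_peaks = RegionSet([GenomicInterval("chr1", 1050, 2050)])
    nf_frags = _fragments(
        [GenomicInterval("chr1", 1400, 1600)] * 1, "nf", 1_000_000
    )
    # 5 CAF fragments at the locus vs 1 NF: FC (6)/(2) = 3 with pseudocount
    caf_frags = _fragments(
        [GenomicInterval("chr1", 1400 + i, 1600 + i) for i in range(5)],
        "caf",
        1_000_000,
    )
    inc, dec = per_patient_changed_peaks(nf_peaks, caf_peaks, nf_frags, caf_frags)
    assert len(inc) == 1 and len(dec) == 0
    inc2, dec2 = per_patient_changed_peaks(caf_peaks, nf_peaks, caf_frags, nf_frags)
    assert len(inc2) == 0 and len(dec2) == 1


def test_per_patient_identical_samples_yield_nothing():
    peaks = RegionSet([GenomicInterval("chr1", 0, 1000)])
    frags = _fragments([GenomicInterval("chr1", 400, 600)], "nf", 10_000)
    frags2 = FragmentSet("caf", "H3K27ac", frags.fragments, 10_000)
    inc, dec = per_patient_changed_peaks(peaks, peaks, frags, frags2)
    assert len(inc) == 0 and len(dec) == 0


# ---------------------------------------------------------------------------
# top_changed_regions
# ---------------------------------------------------------------------------

def test_top_changed_regions_against_full_sort():
    rng = np.random.default_rng(21)
    design = six_pair_design()
    n = 60
    values = pd.DataFrame(
        {s: rng.uniform(0.5, 8.0, n) for s in design.all_samples}
    )
    m = matrix_from_values(values)
    # genes make ~half the regions promoters
    genes = [
        GeneAnnotation(f"g{i}", "chr1", int(rng.integers(0, 60_000)), "+")
        for i in range(15)
    ]
    from cafcall import classify_promoters, paired_fold_change

    labels = classify_promoters(m.regions, genes, 1000)
    fc_sum = paired_fold_change(m, design).sum(axis=1)
    for stratum in ("promoter", "non_promoter"):
        stratum_ivs = [iv for iv, l in zip(m.regions, labels) if l == stratum]
        if len(stratum_ivs) < 3:
            continue
        k = len(stratum_ivs) // 2
        expected = sorted(
            stratum_ivs, key=lambda iv: (-fc_sum[iv.region_id], iv.chrom, iv.start)
        )[:k]
        got = top_changed_regions(m, design, genes, k=k, stratum=stratum)
        assert set(got.region_ids) == {iv.region_id for iv in expected}
        # k = stratum size returns the whole stratum
        full = top_changed_regions(m, design, genes, k=len(stratum_ivs), stratum=stratum)
        assert set(full.region_ids) == {iv.region_id for iv in stratum_ivs}
        with pytest.raises(ValueError):
            top_changed_regions(m, design, genes, k=len(stratum_ivs) + 1, stratum=stratum)


# ---------------------------------------------------------------------------
# active enhancers
# ---------------------------------------------------------------------------

def test_active_enhancers_one_bp_rule():
    k27 = RegionSet([GenomicInterval("chr1", 100, 300)])
    assert len(active_enhancers(k27, RegionSet([GenomicInterval("chr1", 299, 400)]))) == 1
    assert len(active_enhancers(k27, RegionSet([GenomicInterval("chr1", 300, 400)]))) == 0
    assert len(active_enhancers(k27, RegionSet([]))) == 0


def test_active_enhancers_matches_all_pairs_oracle():
    rng = np.random.default_rng(13)
    for _ in range(25):
        k27 = RegionSet(
            [
                GenomicInterval(
                    str(rng.choice(["chr1", "chr2"])),
                    s := int(rng.integers(0, 4000)),
                    s + int(rng.integers(1, 500)),
                )
                for _ in range(int(rng.integers(1, 25)))
            ]
        )
        k4 = RegionSet(
            [
                GenomicInterval(
                    str(rng.choice(["chr1", "chr2"])),
                    s := int(rng.integers(0, 4000)),
                    s + int(rng.integers(1, 500)),
                )
                for _ in range(int(rng.integers(1, 25)))
            ]
        )
        min_bp = int(rng.integers(1, 50))
        expected = {
            (p.chrom, p.start, p.end)
            for p in k27
            if any(
                p.chrom == q.chrom
                and min(p.end, q.end) - max(p.start, q.start) >= min_bp
                for q in k4
            )
        }
        got = {(p.chrom, p.start, p.end) for p in active_enhancers(k27, k4, min_bp)}
        assert got == expected


# ---------------------------------------------------------------------------
# consensus caller
# ---------------------------------------------------------------------------

def test_consensus_pass_count_boundary():
    m, design = matrix_with_fc([[4, 4, 4, 4, 1, 1], [4, 4, 4, 1, 1, 1]])
    _, _, _, act, rep, mp = consensus_masks(m, design)
    assert mp == 4
    assert act.tolist() == [True, False]   # 4 pairs pass ">3"; 3 do not
    assert not rep.any()


def test_consensus_monotone_in_thresholds():
    rng = np.random.default_rng(77)
    design = six_pair_design()
    m = matrix_from_values(
        pd.DataFrame({s: rng.uniform(0.2, 10.0, 200) for s in design.all_samples})
    )
    base = consensus_masks(m, design, ConsensusParams(fc_up=2.0, fc_down=0.5))
    stricter_fc = consensus_masks(m, design, ConsensusParams(fc_up=3.0, fc_down=1 / 3))
    stricter_mp = consensus_masks(
        m, design, ConsensusParams(fc_up=2.0, fc_down=0.5, min_pairs=5)
    )
    for strict in (stricter_fc, stricter_mp):
        assert (strict[3] <= base[3]).all()  # activated never grows
        assert (strict[4] <= base[4]).all()  # repressed never grows


def test_consensus_symmetry_under_design_swap():
    rng = np.random.default_rng(78)
    design = six_pair_design()
    m = matrix_from_values(
        pd.DataFrame({s: rng.uniform(0.2, 10.0, 300) for s in design.all_samples})
    )
    params = ConsensusParams(fc_up=2.0, fc_down=0.5)  # fc_down = 1/fc_up
    _, _, _, act, rep, _ = consensus_masks(m, design, params)
    _, _, _, act_sw, rep_sw, _ = consensus_masks(m, design.swapped(), params)
    assert act.equals(rep_sw)
    assert rep.equals(act_sw)


def test_consensus_self_consistent_bitmaps_on_cohort(consensus_run):
    result, _ = consensus_run
    up_counts = result.pass_up.sum(axis=1)
    for rid in result.activated.region_ids:
        assert up_counts[rid] >= result.min_pairs_used
    down_counts = result.pass_down.sum(axis=1)
    for rid in result.repressed.region_ids:
        assert down_counts[rid] >= result.min_pairs_used
    assert set(result.activated.region_ids).isdisjoint(result.repressed.region_ids)


def test_call_consensus_requires_all_samples():
    design = six_pair_design()
    with pytest.raises(ValueError, match="active-enhancer sets missing"):
        call_consensus_enhancers({}, {}, design)


# ---------------------------------------------------------------------------
# expression association
# ---------------------------------------------------------------------------

def test_expression_association_detects_coupling(cohort, consensus_run):
    from cafcall import read_gene_table

    result, design = consensus_run
    genes = read_gene_table(cohort.genes_path)
    report = expression_association(
        result, genes, cohort.expression, design, rng=np.random.default_rng(7)
    )
    assert (report["p_value"] < 0.01).sum() >= 5
    assert (report["effect"] > 0).all()


def test_expression_association_null_is_flat():
    # identical NF/CAF expression: no patient should show enrichment
    rng = np.random.default_rng(5)
    design = PairedDesign({f"P{i}": (f"nf{i}", f"caf{i}") for i in range(1, 4)})
    regions = RegionSet(
        [GenomicInterval("chr1", i * 2000, i * 2000 + 800) for i in range(40)]
    )
    genes = [GeneAnnotation(f"g{i}", "chr1", i * 2000 + 400, "+") for i in range(40)]
    base = rng.lognormal(1, 1, 40)
    expr = pd.DataFrame(
        {s: base for p in design.pairs.values() for s in p},
        index=[g.gene_id for g in genes],
    )
    values = pd.DataFrame(
        {s: rng.uniform(1, 2, 40) for s in design.all_samples},
        index=regions.region_ids,
    )
    m = EnrichmentMatrix(regions=regions, values=values)
    from cafcall.enhancers import EnhancerCallResult, ConsensusParams

    act = RegionSet(list(regions)[:10])
    result = EnhancerCallResult(
        all_enhancers=regions,
        activated=act,
        repressed=RegionSet([]),
        fc_table=values,
        pass_up=values > 0,
        pass_down=values > 1e9,
        matrix=m,
        params=ConsensusParams(),
        min_pairs_used=2,
    )
    report = expression_association(
        result, genes, expr, design, rng=np.random.default_rng(2)
    )
    # identical columns -> log2 FC all zero -> rank-sum p = 0.5 exactly-ish
    assert (report["p_value"] > 0.05).all()
    assert np.allclose(report["effect"], 0.0)


def test_expression_association_degenerate_gene_set_errors(consensus_run, cohort):
    from cafcall import read_gene_table

    result, design = consensus_run
    genes = read_gene_table(cohort.genes_path)
    single = cohort.expression.iloc[:1]
    with pytest.raises(ValueError):
        expression_association(result, genes, single, design)
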