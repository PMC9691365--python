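"""Deterministic synthetic paired NF/CAF cohort with planted ground truth.

The generator emulates the statistical structure the analysis assumes:

* per-patient NF/CAF pairs with H3K27ac and H3K4me1 fragment data;
* H3K4me1 peaks identical within a pair at every enhancer locus (primed
  enhancers are preset and maintained);
* a subset of loci with elevated CAF H3K27ac density (activated, default
  fold 4) and a subset with reduced density (repressed, default fold 0.25);
* per-patient effect dropout modelling inter-patient heterogeneity, so the
  "in more than k pairs" consensus logic is genuinely exercised;
* AP-1 consensus sites planted near activated-enhancer centers in an
  otherwise i.i.d.-uniform genome;
* expression of the nearest genes of realized activated loci shifted in the
  CAF columns, plus a separate RNA-only paired design with planted
  signature genes and an "invasive vs normal stroma" two-group matrix.

Fragment sampling is per-locus Poisson signal on a uniform genomic
background; there is no GC, mappability or duplicate model.  Identical
seeds produce byte-identical files.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .intervals import (
    GeneAnnotation,
    GenomicInterval,
    RegionSet,
    nearest_genes,
    read_bed,
    write_bed,
    write_gene_table,
)
from .quant import FragmentSet, PairedDesign, read_fragment_table, read_sample_metadata

__all__ = ["CohortSpec", "PlantedTruth", "generate", "load_cohort", "SyntheticCohort"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AP1_VARIANTS = ("TGACTCA", "TGAGTCA")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort.

    Effect sizes, sample counts and noise levels default to the study
    conditions the pipeline targets: six NF/CAF pairs profiled for two
    histone marks, a seven-pair RNA-only design, fourfold activation /
    fourfold repression of planted enhancer loci, and a one-in-six chance
    that a planted effect is absent in any given patient.
    """

    seed: int = 17
    n_patients: int = 6
    genome: tuple[tuple[str, int], ...] = (("chr1", 5_000_000), ("chr2", 5_000_000))
    n_genes: int = 800
    n_enhancer_loci: int = 2000
    n_activated: int = 300
    n_repressed: int = 150
    activation_fc: float = 4.0
    repression_fc: float = 0.25
    effect_dropout: float = 1.0 / 6.0
    depth: int = 200_000
    fragment_length_mean: float = 200.0
    fragment_length_sd: float = 30.0
    peak_width_mean: float = 1000.0
    peak_width_sd: float = 200.0
    motif_plant_rate: float = 0.7
    expression_coupling_log2fc: float = 1.5
    expression_noise_sigma: float = 0.4
    n_signature_genes: int = 100
    n_rna_patients: int = 7
    # --- secondary knobs (documented defaults, rarely moved) ---
    locus_budget_fraction: float = 0.75   # fraction of depth at enhancer loci
    tech_noise_sigma_log2: float = 0.1    # per-sample technical expression noise
    signature_fc: float = 3.0             # planted signature fold change
    signature_pairs: int = 5              # pairs in which a signature gene is planted
    n_noise_peaks: int = 50               # spurious peak calls per sample per mark
    peak_jitter_bp: int = 50              # per-patient peak boundary jitter
    min_locus_gap: int = 1500             # enforced gap between locus edges
    edge_margin: int = 2000               # keep loci away from chromosome ends
    motif_mismatch_rate: float = 0.2      # planted sites carrying one mismatch

    def __post_init__(self) -> None:
        if not 0 <= self.effect_dropout < 1:
            raise ValueError("effect_dropout must be in [0, 1)")
        if not self.repression_fc < 1 < self.activation_fc:
            raise ValueError("need repression_fc < 1 < activation_fc")
        if self.n_activated + self.n_repressed > self.n_enhancer_loci:
            raise ValueError("more effect loci than enhancer loci")
        for name in (
            "n_patients", "n_genes", "n_enhancer_loci", "depth",
            "n_signature_genes", "n_rna_patients",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 1 <= self.signature_pairs <= self.n_rna_patients:
            raise ValueError("signature_pairs must fit the RNA design")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["genome"] = [list(g) for g in self.genome]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        d = yaml.safe_load(Path(path).read_text())
        d["genome"] = tuple((str(c), int(L)) for c, L in d["genome"])
        return cls(**d)


@dataclass
class PlantedTruth:
    """Ground-truth labels and realizations emitted alongside the cohort."""

    spec: CohortSpec
    loci: RegionSet                      # all enhancer loci
    labels: list[str]                    # activated | repressed | neutral per locus
    nearest: list[str]                   # nearest gene id per locus
    realized: dict[str, list[str]]       # locus region_id -> patients with effect
    motif_plants: list[dict]             # chrom,pos,strand,region_id,mismatched
    signature_genes: list[str]
    rna_realized_pairs: dict[str, list[str]]
    design: PairedDesign
    rna_design: PairedDesign
    stroma_groups: dict[str, list[str]]
    out_dir: Path

    def loci_with_label(self, label: str) -> RegionSet:
        return RegionSet(
            [iv for iv, lab in zip(self.loci, self.labels) if lab == label],
            label=label,
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.spec.seed,
            "loci": [
                {
                    "region_id": iv.region_id,
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "label": lab,
                    "nearest_gene": gene,
                }
                for iv, lab, gene in zip(self.loci, self.labels, self.nearest)
            ],
            "realized": self.realized,
            "motif_plants": self.motif_plants,
            "signature_genes": self.signature_genes,
            "rna_realized_pairs": self.rna_realized_pairs,
            "design": {p: list(v) for p, v in self.design.pairs.items()},
            "rna_design": {p: list(v) for p, v in self.rna_design.pairs.items()},
            "stroma_groups": self.stroma_groups,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path, spec: CohortSpec | None = None) -> "PlantedTruth":
        d = json.loads(Path(path).read_text())
        loci = RegionSet(
            [GenomicInterval(x["chrom"], x["start"], x["end"]) for x in d["loci"]],
            label="loci",
        )
        order = {iv.region_id: i for i, iv in enumerate(loci)}
        labels = [""] * len(loci)
        nearest = [""] * len(loci)
        for x in d["loci"]:
            labels[order[x["region_id"]]] = x["label"]
            nearest[order[x["region_id"]]] = x["nearest_gene"]
        return cls(
            spec=spec or CohortSpec(seed=d["seed"]),
            loci=loci,
            labels=labels,
            nearest=nearest,
            realized={k: list(v) for k, v in d["realized"].items()},
            motif_plants=d["motif_plants"],
            signature_genes=list(d["signature_genes"]),
            rna_realized_pairs={k: list(v) for k, v in d["rna_realized_pairs"].items()},
            design=PairedDesign({p: tuple(v) for p, v in d["design"].items()}),
            rna_design=PairedDesign({p: tuple(v) for p, v in d["rna_design"].items()}),
            stroma_groups={k: list(v) for k, v in d["stroma_groups"].items()},
            out_dir=Path(path).parent,
        )

    # -- evaluation against calls ------------------------------------------

    def _overlaps_label(self, regions: RegionSet, label: str) -> np.ndarray:
        return _overlaps_any(regions, self.loci_with_label(label))

    def recall_precision(self, called: RegionSet, label: str) -> tuple[float, float]:
        """Recovery of planted loci of one label by a called region set.

        Recall: fraction of planted loci overlapped (>=1 bp) by a called
        region; precision: fraction of called regions overlapping a planted
        locus of that label.
        """
        truth = self.loci_with_label(label)
        if len(truth) == 0:
            return float("nan"), float("nan")
        recall = float(np.mean(_overlaps_any(truth, called))) if len(called) else 0.0
        precision = (
            float(np.mean(_overlaps_any(called, truth))) if len(called) else float("nan")
        )
        return recall, precision


def _overlaps_any(queries: RegionSet, targets: RegionSet) -> np.ndarray:
    """Boolean per query: does it overlap (>=1 bp) any target interval?"""
    by_chrom = targets.by_chrom()
    arrays = {
        chrom: (
            np.array([iv.start for iv in ivs], dtype=np.int64),
            np.array([iv.end for iv in ivs], dtype=np.int64),
        )
        for chrom, ivs in by_chrom.items()
    }
    out = np.zeros(len(queries), dtype=bool)
    for i, q in enumerate(queries):
        if q.chrom not in arrays:
            continue
        starts, ends = arrays[q.chrom]
        # targets sorted by start; candidates are the last one starting at or
        # before q.start and anything starting inside [q.start, q.end)
        j = int(np.searchsorted(starts, q.start, side="right")) - 1
        hit = j >= 0 and ends[j] > q.start
        if not hit:
            k = int(np.searchsorted(starts, q.start, side="right"))
            hit = k < len(starts) and starts[k] < q.end
        out[i] = bool(hit)
    return out


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _place_loci(spec: CohortSpec, rng: np.random.Generator) -> RegionSet:
    """Non-overlapping enhancer loci with an enforced gap, or error."""
    chrom_names = [c for c, _ in spec.genome]
    lengths = np.array([L for _, L in spec.genome], dtype=float)
    probs = lengths / lengths.sum()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    loci = []
    for _ in range(spec.n_enhancer_loci):
        width = int(np.clip(rng.normal(spec.peak_width_mean, spec.peak_width_sd), 300, None))
        placed = False
        for _attempt in range(1000):
            ci = int(rng.choice(len(chrom_names), p=probs))
            chrom, L = chrom_names[ci], int(lengths[ci])
            lo, hi = spec.edge_margin, L - spec.edge_margin - width
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            end = start + width
            occ = occupied[chrom]
            j = bisect.bisect_left(occ, (start, end))
            ok = True
            if j > 0 and occ[j - 1][1] + spec.min_locus_gap > start:
                ok = False
            if ok and j < len(occ) and end + spec.min_locus_gap > occ[j][0]:
                ok = False
            if ok:
                bisect.insort(occ, (start, end))
                loci.append(GenomicInterval(chrom, start, end))
                placed = True
                break
        if not placed:
            raise RuntimeError(
                "could not place a locus without overlap after 1000 attempts; "
                "use a larger genome or fewer loci"
            )
    return RegionSet(loci, label="loci")


def _place_genes(
    spec: CohortSpec, rng: np.random.Generator
) -> list[GeneAnnotation]:
    chrom_names = [c for c, _ in spec.genome]
    lengths = np.array([L for _, L in spec.genome], dtype=float)
    probs = lengths / lengths.sum()
    width = len(str(spec.n_genes))
    genes = []
    used: set[tuple[str, int]] = set()
    for i in range(spec.n_genes):
        # guarantee at least one gene per chromosome, then proportional
        ci = i if i < len(chrom_names) else int(rng.choice(len(chrom_names), p=probs))
        chrom, L = chrom_names[ci], int(lengths[ci])
        tss = int(rng.integers(1000, L - 1000))
        while (chrom, tss) in used:  # avoid exact TSS ties
            tss = int(rng.integers(1000, L - 1000))
        used.add((chrom, tss))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneAnnotation(f"G{i + 1:0{width}d}", chrom, tss, strand))
    return genes


def _plant_motifs(
    seqs: dict[str, np.ndarray],
    loci: RegionSet,
    labels: Sequence[str],
    spec: CohortSpec,
    rng: np.random.Generator,
) -> list[dict]:
    """Write AP-1 consensus variants into the genome near activated centers."""
    plants = []
    w = 7
    for iv, lab in zip(loci, labels):
        if lab != "activated":
            continue
        if rng.random() >= spec.motif_plant_rate:
            continue
        site = _AP1_VARIANTS[int(rng.integers(0, 2))]
        mismatched = rng.random() < spec.motif_mismatch_rate
        if mismatched:
            pos = int(rng.integers(0, w))
            alts = [b for b in "ACGT" if b != site[pos]]
            site = site[:pos] + alts[int(rng.integers(0, 3))] + site[pos + 1 :]
        strand = "+" if rng.random() < 0.5 else "-"
        planted = site if strand == "+" else site.translate(_COMPLEMENT)[::-1]
        start = iv.center + int(rng.integers(-50, 51 - w))
        seqs[iv.chrom][start : start + w] = np.frombuffer(
            planted.encode("ascii"), dtype=np.uint8
        )
        plants.append(
            {
                "region_id": iv.region_id,
                "chrom": iv.chrom,
                "pos": start,
                "strand": strand,
                "mismatched": mismatched,
            }
        )
    return plants


def _write_fasta(seqs: Mapping[str, np.ndarray], path: Path) -> None:
    with path.open("w") as fh:
        for chrom in seqs:
            fh.write(f">{chrom}\n")
            raw = seqs[chrom].tobytes().decode("ascii")
            for i in range(0, len(raw), 60):
                fh.write(raw[i : i + 60] + "\n")


def _sample_fragments(
    locus_rates: np.ndarray,
    peak_starts: np.ndarray,
    peak_ends: np.ndarray,
    locus_chrom_idx: np.ndarray,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Poisson per-locus signal plus uniform genomic background."""
    chrom_names = [c for c, _ in spec.genome]
    lengths = np.array([L for _, L in spec.genome], dtype=np.int64)
    probs = lengths / lengths.sum()

    locus_counts = rng.poisson(locus_rates)
    ref = np.repeat(np.arange(len(locus_rates)), locus_counts)
    mids_sig = peak_starts[ref] + rng.random(len(ref)) * (peak_ends[ref] - peak_starts[ref])
    chrom_sig = locus_chrom_idx[ref]

    n_bg = rng.poisson((1.0 - spec.locus_budget_fraction) * spec.depth)
    chrom_bg = rng.choice(len(chrom_names), size=n_bg, p=probs)
    mids_bg = rng.random(n_bg) * lengths[chrom_bg]

    chrom_idx = np.concatenate([chrom_sig, chrom_bg])
    mids = np.concatenate([mids_sig, mids_bg])
    n = len(mids)
    frag_len = np.clip(
        rng.normal(spec.fragment_length_mean, spec.fragment_length_sd, size=n), 50, None
    ).astype(np.int64)
    starts = np.maximum((mids - frag_len / 2).astype(np.int64), 0)
    ends = np.minimum(starts + frag_len, lengths[chrom_idx])
    starts = np.minimum(starts, ends - 1)  # keep end > start at chromosome edges

    df = pd.DataFrame(
        {
            "chrom": np.array(chrom_names, dtype=object)[chrom_idx],
            "start": starts,
            "end": ends,
        }
    )
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
        drop=True
    )


def _noise_peaks(spec: CohortSpec, rng: np.random.Generator) -> list[GenomicInterval]:
    chrom_names = [c for c, _ in spec.genome]
    lengths = np.array([L for _, L in spec.genome], dtype=np.int64)
    probs = lengths / lengths.sum()
    out = []
    for _ in range(spec.n_noise_peaks):
        ci = int(rng.choice(len(chrom_names), p=probs))
        width = int(np.clip(rng.normal(spec.peak_width_mean, spec.peak_width_sd), 300, None))
        start = int(rng.integers(0, max(1, lengths[ci] - width)))
        out.append(GenomicInterval(chrom_names[ci], start, start + width))
    return out


def _expression_matrix(
    gene_ids: Sequence[str],
    columns: Sequence[str],
    pair_of_column: Mapping[str, str],
    is_caf_column: Mapping[str, bool],
    shifted: Mapping[str, Mapping[str, float]],  # pair -> gene -> log2 shift
    spec: CohortSpec,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Lognormal baseline x patient effect (shared within pair) x tech noise."""
    n_genes = len(gene_ids)
    baseline = rng.lognormal(mean=1.5, sigma=1.0, size=n_genes)
    pairs = sorted(set(pair_of_column.values()))
    patient_effect = {
        p: np.exp(rng.normal(0.0, spec.expression_noise_sigma, size=n_genes))
        for p in pairs
    }
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    data = {}
    for col in columns:
        pair = pair_of_column[col]
        values = baseline * patient_effect[pair]
        values = values * 2 ** rng.normal(0.0, spec.tech_noise_sigma_log2, size=n_genes)
        if is_caf_column[col]:
            for gene, shift in shifted.get(pair, {}).items():
                values[gene_pos[gene]] *= 2.0 ** shift
        data[col] = values
    return pd.DataFrame(data, index=list(gene_ids))


def generate(spec: CohortSpec, out_dir: str | Path) -> PlantedTruth:
    """Generate the full cohort on disk and return the planted truth.

    Emits genome FASTA, gene annotation TSV, per-sample peak and fragment
    BEDs with a metadata TSV, the paired expression matrix, the RNA-only
    seven-pair matrix, the two-group stroma matrix, the cohort spec as YAML
    and the truth as JSON.  Identical seeds give byte-identical files.
    """
    out = Path(out_dir)
    (out / "fragments").mkdir(parents=True, exist_ok=True)
    (out / "peaks").mkdir(exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    # genome
    seqs = {c: _BASES[rng.integers(0, 4, size=L)].copy() for c, L in spec.genome}

    # loci, labels, genes
    loci = _place_loci(spec, rng)
    perm = rng.permutation(spec.n_enhancer_loci)
    labels = ["neutral"] * spec.n_enhancer_loci
    for i in perm[: spec.n_activated]:
        labels[i] = "activated"
    for i in perm[spec.n_activated : spec.n_activated + spec.n_repressed]:
        labels[i] = "repressed"
    genes = _place_genes(spec, rng)
    nearest = nearest_genes(loci, genes)

    plants = _plant_motifs(seqs, loci, labels, spec, rng)
    _write_fasta(seqs, out / "genome.fa")
    write_gene_table(genes, out / "genes.tsv")

    chrom_index = {c: i for i, (c, _) in enumerate(spec.genome)}
    locus_chrom_idx = np.array([chrom_index[iv.chrom] for iv in loci])
    locus_starts = np.array([iv.start for iv in loci], dtype=np.int64)
    locus_ends = np.array([iv.end for iv in loci], dtype=np.int64)
    lam_base = spec.locus_budget_fraction * spec.depth / spec.n_enhancer_loci

    patients = [f"P{i + 1}" for i in range(spec.n_patients)]
    design = PairedDesign({p: (f"{p}_NF", f"{p}_CAF") for p in patients})

    # per-patient effect realization (dropout)
    realized_mask = np.zeros((spec.n_enhancer_loci, spec.n_patients), dtype=bool)
    for i, lab in enumerate(labels):
        if lab in ("activated", "repressed"):
            realized_mask[i] = rng.random(spec.n_patients) >= spec.effect_dropout
    realized = {
        loci[i].region_id: [patients[j] for j in range(spec.n_patients) if realized_mask[i, j]]
        for i in range(spec.n_enhancer_loci)
        if labels[i] != "neutral"
    }

    meta_rows = []
    for pi, patient in enumerate(patients):
        jitter = rng.integers(-spec.peak_jitter_bp, spec.peak_jitter_bp + 1,
                              size=spec.n_enhancer_loci)
        pstarts = locus_starts + jitter
        pends = locus_ends + jitter
        # spurious H3K4me1 calls are pair-stable (the mark is preset in NFs
        # and maintained), unlike the sample-specific H3K27ac noise below
        k4_noise = _noise_peaks(spec, rng)
        for condition in ("NF", "CAF"):
            sample = f"{patient}_{condition}"
            # CAF H3K27ac rate multiplier per locus
            mult = np.ones(spec.n_enhancer_loci)
            if condition == "CAF":
                for i, lab in enumerate(labels):
                    if not realized_mask[i, pi]:
                        continue
                    if lab == "activated":
                        mult[i] = spec.activation_fc
                    elif lab == "repressed":
                        mult[i] = spec.repression_fc
            for mark in ("H3K27ac", "H3K4me1"):
                rates = lam_base * (mult if mark == "H3K27ac" else np.ones(spec.n_enhancer_loci))
                frags = _sample_fragments(
                    rates, pstarts, pends, locus_chrom_idx, spec, rng
                )
                frag_path = f"fragments/{sample}.{mark}.bed"
                frags.to_csv(out / frag_path, sep="\t", header=False, index=False)
                # peaks: locus peak emitted where the expected local density
                # supports a call (>= half the base rate), plus spurious calls
                keep = rates >= 0.5 * lam_base
                peak_ivs = [
                    GenomicInterval(loci[i].chrom, int(pstarts[i]), int(pends[i]))
                    for i in range(spec.n_enhancer_loci)
                    if keep[i]
                ]
                peak_ivs.extend(k4_noise if mark == "H3K4me1" else _noise_peaks(spec, rng))
                peak_path = f"peaks/{sample}.{mark}.bed"
                write_bed(RegionSet(peak_ivs, label=f"{sample}:{mark}"), out / peak_path, columns=3)
                meta_rows.append(
                    {
                        "sample_id": sample,
                        "patient": patient,
                        "condition": condition,
                        "mark": mark,
                        "total_unique": len(frags),
                        "path": frag_path,
                        "peak_path": peak_path,
                    }
                )
    meta = pd.DataFrame(meta_rows)
    meta.to_csv(out / "samples.tsv", sep="\t", index=False)

    # paired expression coupled to realized activated loci
    gene_ids = [g.gene_id for g in genes]
    shifted: dict[str, dict[str, float]] = {p: {} for p in patients}
    for i, lab in enumerate(labels):
        if lab != "activated":
            continue
        for j, patient in enumerate(patients):
            if realized_mask[i, j]:
                shifted[patient][nearest[i]] = spec.expression_coupling_log2fc
    columns = [s for p in patients for s in design.pairs[p]]
    expr = _expression_matrix(
        gene_ids,
        columns,
        {s: p for p in patients for s in design.pairs[p]},
        {s: s.endswith("_CAF") for s in columns},
        shifted,
        spec,
        rng,
    )
    expr.round(4).to_csv(out / "expression.tsv", sep="\t", index_label="gene_id",
                         float_format="%.4f")

    # RNA-only seven-pair design with planted signature genes
    rna_patients = [f"R{i + 1}" for i in range(spec.n_rna_patients)]
    rna_design = PairedDesign({p: (f"{p}_NF", f"{p}_CAF") for p in rna_patients})
    sig_idx = rng.choice(spec.n_genes, size=spec.n_signature_genes, replace=False)
    signature_genes = sorted(gene_ids[i] for i in sig_idx)
    rna_realized: dict[str, list[str]] = {}
    rna_shifted: dict[str, dict[str, float]] = {p: {} for p in rna_patients}
    for gene in signature_genes:
        chosen = rng.choice(spec.n_rna_patients, size=spec.signature_pairs, replace=False)
        pairs = sorted(rna_patients[j] for j in chosen)
        rna_realized[gene] = pairs
        for p in pairs:
            rna_shifted[p][gene] = float(np.log2(spec.signature_fc))
    rna_columns = [s for p in rna_patients for s in rna_design.pairs[p]]
    rna_expr = _expression_matrix(
        gene_ids,
        rna_columns,
        {s: p for p in rna_patients for s in rna_design.pairs[p]},
        {s: s.endswith("_CAF") for s in rna_columns},
        rna_shifted,
        spec,
        rng,
    )
    rna_expr.round(4).to_csv(out / "rna_expression.tsv", sep="\t",
                             index_label="gene_id", float_format="%.4f")

    # independent two-group stroma dataset (signature genes shifted only)
    n_per_group = 10
    normal_cols = [f"normal_{i + 1:02d}" for i in range(n_per_group)]
    invasive_cols = [f"invasive_{i + 1:02d}" for i in range(n_per_group)]
    stroma_cols = normal_cols + invasive_cols
    stroma_shift = {
        col: {g: spec.expression_coupling_log2fc for g in signature_genes}
        for col in invasive_cols
    }
    stroma = _expression_matrix(
        gene_ids,
        stroma_cols,
        {c: c for c in stroma_cols},  # every column its own "pair": unpaired design
        {c: c in set(invasive_cols) for c in stroma_cols},
        stroma_shift,
        spec,
        rng,
    )
    stroma.round(4).to_csv(out / "stroma_expression.tsv", sep="\t",
                           index_label="gene_id", float_format="%.4f")

    truth = PlantedTruth(
        spec=spec,
        loci=loci,
        labels=labels,
        nearest=nearest,
        realized=realized,
        motif_plants=plants,
        signature_genes=signature_genes,
        rna_realized_pairs=rna_realized,
        design=design,
        rna_design=rna_design,
        stroma_groups={"normal": normal_cols, "invasive": invasive_cols},
        out_dir=out,
    )
    truth.to_json(out / "truth.json")
    spec.to_yaml(out / "cohort_spec.yaml")
    return truth


# ---------------------------------------------------------------------------
# loading a generated cohort
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """Handles to all on-disk pieces of a generated cohort."""

    out_dir: Path
    meta: pd.DataFrame
    design: PairedDesign
    genes_path: Path
    fasta_path: Path
    expression: pd.DataFrame
    rna_expression: pd.DataFrame
    stroma_expression: pd.DataFrame
    truth: PlantedTruth

    def fragment_sets(self, mark: str) -> dict[str, FragmentSet]:
        rows = self.meta[self.meta["mark"] == mark]
        return {
            str(r.sample_id): FragmentSet(
                sample_id=str(r.sample_id),
                mark=mark,
                fragments=read_fragment_table(self.out_dir / r.path),
                total_unique=int(r.total_unique),
            )
            for r in rows.itertuples()
        }

    def peak_sets(self, mark: str) -> dict[str, RegionSet]:
        rows = self.meta[self.meta["mark"] == mark]
        return {
            str(r.sample_id): read_bed(
                self.out_dir / r.peak_path, label=f"{r.sample_id}:{mark}"
            )
            for r in rows.itertuples()
        }


def load_cohort(out_dir: str | Path) -> SyntheticCohort:
    out = Path(out_dir)
    meta = read_sample_metadata(out / "samples.tsv")
    truth = PlantedTruth.from_json(out / "truth.json",
                                   spec=CohortSpec.from_yaml(out / "cohort_spec.yaml"))
    read = lambda name: pd.read_csv(out / name, sep="\t", index_col="gene_id")
    return SyntheticCohort(
        out_dir=out,
        meta=meta,
        design=truth.design,
        genes_path=out / "genes.tsv",
        fasta_path=out / "genome.fa",
        expression=read("expression.tsv"),
        rna_expression=read("rna_expression.tsv"),
        stroma_expression=read("stroma_expression.tsv"),
        truth=truth,
    )
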