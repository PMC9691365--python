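"""End-to-end drivers tying the modules together on a cohort directory.

Any directory with a ``samples.tsv`` metadata table (sample_id, patient,
condition, mark, total_unique, path, peak_path) can be run: active
enhancers are derived per sample from the H3K27ac and H3K4me1 peak files,
H3K27ac fragments are re-quantified on the merged union, and the paired
consensus caller produces the activated / repressed sets.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .enhancers import ConsensusParams, EnhancerCallResult, active_enhancers, call_consensus_enhancers
from .intervals import RegionSet, read_bed
from .quant import FragmentSet, PairedDesign, read_fragment_table, read_sample_metadata

__all__ = ["run_consensus_from_metadata", "load_mark"]


def load_mark(
    meta: pd.DataFrame, base_dir: str | Path, mark: str
) -> tuple[dict[str, FragmentSet], dict[str, RegionSet]]:
    """Fragment sets and peak sets of one histone mark, keyed by sample."""
    base = Path(base_dir)
    rows = meta[meta["mark"] == mark]
    if rows.empty:
        raise ValueError(f"no samples with mark {mark!r} in metadata")
    frags = {}
    peaks = {}
    for r in rows.itertuples():
        sid = str(r.sample_id)
        frags[sid] = FragmentSet(
            sample_id=sid,
            mark=mark,
            fragments=read_fragment_table(base / r.path),
            total_unique=int(r.total_unique),
        )
        peaks[sid] = read_bed(base / r.peak_path, label=f"{sid}:{mark}")
    return frags, peaks


def run_consensus_from_metadata(
    cohort_dir: str | Path,
    params: ConsensusParams = ConsensusParams(),
) -> tuple[EnhancerCallResult, PairedDesign]:
    """Full consensus enhancer call from a cohort directory."""
    base = Path(cohort_dir)
    meta = read_sample_metadata(base / "samples.tsv")
    if "peak_path" not in meta.columns:
        raise ValueError("metadata needs a peak_path column")
    design = PairedDesign.from_metadata(
        meta[meta["mark"] == "H3K27ac"][["sample_id", "patient", "condition"]]
    )
    k27_frags, k27_peaks = load_mark(meta, base, "H3K27ac")
    _, k4_peaks = load_mark(meta, base, "H3K4me1")
    active = {
        sid: active_enhancers(k27_peaks[sid], k4_peaks[sid], params.min_overlap_bp)
        for sid in design.all_samples
    }
    result = call_consensus_enhancers(active, k27_frags, design, params)
    return result, design
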