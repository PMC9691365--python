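"""Shared fixtures: one default synthetic cohort generated per session."""

from __future__ import annotations

import pytest

from cafcall import (
    CohortSpec,
    ConsensusParams,
    generate,
    load_cohort,
    run_consensus_from_metadata,
)


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """Default-condition cohort (6 pairs, 2,000 loci, seed 17) on disk."""
    out = tmp_path_factory.mktemp("cohort") / "default"
    generate(CohortSpec(), out)
    return out


@pytest.fixture(scope="session")
def cohort(cohort_dir):
    return load_cohort(cohort_dir)


@pytest.fixture(scope="session")
def consensus_run(cohort_dir):
    """Consensus enhancer call on the default cohort at default parameters."""
    result, design = run_consensus_from_metadata(cohort_dir, ConsensusParams())
    return result, design


@pytest.fixture(scope="session")
def small_spec():
    """Scaled-down cohort spec for tests that regenerate data repeatedly."""
    return CohortSpec(
        seed=5,
        n_patients=4,
        genome=(("chr1", 400_000),),
        n_genes=60,
        n_enhancer_loci=80,
        n_activated=15,
        n_repressed=8,
        depth=40_000,
        n_signature_genes=12,
        n_rna_patients=5,
        signature_pairs=4,
        n_noise_peaks=5,
    )
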