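"""CAF signature genes, stromal signature scoring and IHC composite scores.

A CAF signature gene is one whose mRNA fold change (CAF / paired NF)
reaches ``fc_min`` (default 2) in at least ``min_pairs`` patients — the
strict majority by default, matching the "in more than 3 pairs" rule of a
seven-pair design.  The signature score of an independent sample is simply
the mean expression of the signature genes detected in that dataset, and
the IHC composite multiplies the 1-4 category for percentage of positive
stromal cells with the 1-4 staining-intensity category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .quant import PairedDesign

__all__ = [
    "SignatureResult",
    "IHCScore",
    "call_signature_genes",
    "signature_score",
    "ihc_composite",
    "INTENSITY_LABELS",
]

#: FPKM pseudocount used in expression fold changes (zeros are common).
DEFAULT_EXPR_EPS = 0.1

INTENSITY_LABELS = ("negative", "weak", "moderate", "strong")


@dataclass
class SignatureResult:
    """Signature gene list plus the per-patient log2 FC heatmap matrix."""

    genes: list[str]
    log2_fc: pd.DataFrame  # signature genes x patients
    fc_min: float
    min_pairs: int
    eps: float


@dataclass(frozen=True)
class IHCScore:
    """Stromal immunostaining score: percentage bin x intensity bin."""

    pct_category: int
    intensity_category: int

    @property
    def composite(self) -> int:
        return self.pct_category * self.intensity_category


def call_signature_genes(
    expr: pd.DataFrame,
    design: PairedDesign,
    fc_min: float = 2.0,
    min_pairs: int | None = None,
    eps: float = DEFAULT_EXPR_EPS,
) -> SignatureResult:
    """Genes with expression FC (CAF/NF) >= fc_min in >= min_pairs patients.

    ``expr`` is a genes x samples table of non-negative FPKM-like values.
    Fold changes are computed on the pseudocounted ratio
    ``(CAF + eps) / (NF + eps)``; thresholding is on the raw ratio, and the
    returned matrix is its log2 (the heatmap substrate), restricted to the
    signature genes.
    """
    if design.n_patients < 1:
        raise ValueError("design has no paired samples")
    missing = [s for s in design.all_samples if s not in expr.columns]
    if missing:
        raise ValueError(f"samples missing from expression matrix: {missing}")
    if (expr[design.all_samples].to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")
    mp = min_pairs if min_pairs is not None else design.n_patients // 2 + 1
    if not 1 <= mp <= design.n_patients:
        raise ValueError(f"min_pairs must be in [1, {design.n_patients}]")

    fc = pd.DataFrame(
        {
            patient: (expr[caf] + eps) / (expr[nf] + eps)
            for patient, (nf, caf) in design.pairs.items()
        },
        index=expr.index,
    )
    qualifies = (fc >= fc_min).sum(axis=1) >= mp
    genes = list(expr.index[qualifies])
    return SignatureResult(
        genes=genes,
        log2_fc=np.log2(fc.loc[genes]),
        fc_min=fc_min,
        min_pairs=mp,
        eps=eps,
    )


def signature_score(
    expr: pd.DataFrame,
    signature_genes: Sequence[str],
    detected: pd.Series | None = None,
) -> pd.Series:
    """Per-sample mean expression of the detected signature genes.

    Signature genes absent from ``expr`` are dropped; so are genes whose
    ``detected`` flag is False, or — when no flag table is given — genes
    that are zero in every sample (the operational meaning of "undetected"
    on array data).  The same gene set is used for all samples.
    """
    present = [g for g in signature_genes if g in expr.index]
    if detected is not None:
        present = [g for g in present if bool(detected.get(g, False))]
    else:
        nonzero = expr.loc[present].sum(axis=1) > 0
        present = [g for g in present if nonzero[g]]
    if not present:
        raise ValueError("no signature gene is detected in this dataset")
    return expr.loc[present].mean(axis=0).rename("caf_signature_score")


def _pct_category(pct: float) -> int:
    if not 0 <= pct <= 100:
        raise ValueError(f"percentage must be within [0, 100], got {pct}")
    for cat, upper in enumerate((25, 50, 75, 100), start=1):
        if pct <= upper:
            return cat
    raise AssertionError("unreachable")


def ihc_composite(pct_positive: float, intensity_label: str) -> IHCScore:
    """Composite IHC score = percentage bin (1-4) x intensity bin (1-4).

    Percentage bins: 0-25, 26-50, 51-75, 76-100 percent of stromal cells
    positive.  Intensity: negative < weak < moderate < strong.
    """
    label = intensity_label.strip().lower()
    if label not in INTENSITY_LABELS:
        raise ValueError(
            f"intensity must be one of {INTENSITY_LABELS}, got {intensity_label!r}"
        )
    return IHCScore(
        pct_category=_pct_category(pct_positive),
        intensity_category=INTENSITY_LABELS.index(label) + 1,
    )


def ihc_score_table(table: pd.DataFrame) -> pd.DataFrame:
    """Batch IHC scoring: needs ``pct_positive`` and ``intensity`` columns."""
    scores = [
        ihc_composite(float(r.pct_positive), str(r.intensity))
        for r in table.itertuples()
    ]
    out = table.copy()
    out["pct_category"] = [s.pct_category for s in scores]
    out["intensity_category"] = [s.intensity_category for s in scores]
    out["composite"] = [s.composite for s in scores]
    return out
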