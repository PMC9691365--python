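"""PWM scanning and central positional enrichment at enhancer centers.

Sequences of fixed length are extracted around region centers (default
±300 bp); each position-weight matrix is scanned for its single best
log-odds site per sequence on either strand (ZOOPS), and motifs whose best
sites concentrate in a central window (default ±100 bp) are flagged by a
one-sided binomial test against the uniform-placement null.  This is a
deliberately simple centrality statistic in the spirit of CentriMo-style
analyses, not a port of any of them.

A "hit" is a best site fully contained in the central window, so the null
success probability is exactly ``(2*central_half - W + 1) / (L - W + 1)``
and the binomial test is calibrated under uniform site placement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta
from scipy import stats

from .intervals import RegionSet

__all__ = [
    "PWM",
    "ap1_pwm",
    "read_jaspar",
    "extract_centered_sequences",
    "scan_best_site",
    "central_enrichment",
    "rank_motifs",
]

logger = logging.getLogger(__name__)

_ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_ALPHABET)}
_PROB_FLOOR = 1e-3


@dataclass(frozen=True)
class PWM:
    """Position probability matrix over A,C,G,T with a background model."""

    motif_id: str
    matrix: np.ndarray          # shape (4, W), columns sum to 1
    background: np.ndarray | None = None  # length 4; default uniform

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != 4 or m.shape[1] < 1:
            raise ValueError("matrix must be 4 x W")
        floored = np.maximum(m, _PROB_FLOOR)
        floored = floored / floored.sum(axis=0, keepdims=True)
        object.__setattr__(self, "matrix", floored)
        bg = (
            np.full(4, 0.25)
            if self.background is None
            else np.asarray(self.background, dtype=float)
        )
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be 4 frequencies summing to 1")
        object.__setattr__(self, "background", bg)
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-6):
            raise AssertionError("columns must sum to 1 after regularization")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self) -> np.ndarray:
        """4 x W log2(p/bg) score matrix."""
        return np.log2(self.matrix / self.background[:, None])

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(
            self.motif_id,
            self.matrix[::-1, ::-1].copy(),
            self.background.copy(),
        )

    def shuffle_columns(self, rng: np.random.Generator) -> "PWM":
        """Column-permuted decoy with identical composition.

        The permutation is resampled until it differs from the identity, so
        a decoy is never the motif itself.
        """
        w = self.width
        perm = rng.permutation(w)
        while w > 1 and np.array_equal(perm, np.arange(w)):
            perm = rng.permutation(w)
        return PWM(
            f"{self.motif_id}_shuf", self.matrix[:, perm].copy(), self.background
        )


def ap1_pwm() -> PWM:
    """AP-1 (JUN/FOS) PWM for the TGA(C/G)TCA consensus.

    Built from the consensus with a dominant-base probability of 0.85
    (0.425/0.425 split at the degenerate C/G position); adequate for
    scanning and ranking without shipping a motif database.
    """
    consensus = ["T", "G", "A", "CG", "T", "C", "A"]
    w = len(consensus)
    m = np.full((4, w), 0.05)
    for j, bases in enumerate(consensus):
        for b in bases:
            m[_BASE_INDEX[b], j] = 0.85 / len(bases) + (0.05 if len(bases) > 1 else 0.0)
    return PWM("AP1", m / m.sum(axis=0, keepdims=True))


def read_jaspar(path: str | Path) -> list[PWM]:
    """Read JASPAR-format count matrices (``>id name`` then 4 base rows).

    Counts are converted to probabilities with a +0.25 pseudocount per cell.
    """
    motifs: list[PWM] = []
    header: str | None = None
    rows: dict[str, list[float]] = {}

    def _flush() -> None:
        nonlocal header, rows
        if header is None:
            return
        if set(rows) != set(_ALPHABET):
            raise ValueError(f"motif {header!r}: need rows for A, C, G and T")
        counts = np.array([rows[b] for b in _ALPHABET], dtype=float) + 0.25
        motifs.append(PWM(header, counts / counts.sum(axis=0, keepdims=True)))
        header, rows = None, {}

    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].split()[0]
            else:
                base, _, rest = line.partition(" ")
                base = base.strip().upper()
                if base not in _BASE_INDEX:
                    raise ValueError(f"unexpected row label {base!r}")
                rows[base] = [
                    float(tok)
                    for tok in rest.replace("[", " ").replace("]", " ").split()
                ]
    _flush()
    if not motifs:
        raise ValueError(f"no motifs found in {path}")
    return motifs


def extract_centered_sequences(
    regions: RegionSet,
    fasta_path: str | Path,
    half_window: int = 300,
) -> list[str]:
    """Uppercase sequences of center ± half_window for each region.

    Regions whose window would run past a chromosome end are dropped with a
    logged warning.  Every returned sequence has length 2*half_window.
    """
    fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    seqs: list[str] = []
    n_dropped = 0
    for iv in regions:
        if iv.chrom not in fasta:
            raise KeyError(f"chromosome {iv.chrom!r} missing from FASTA")
        chrom_len = len(fasta[iv.chrom])
        lo = iv.center - half_window
        hi = iv.center + half_window
        if lo < 0 or hi > chrom_len:
            n_dropped += 1
            continue
        seqs.append(str(fasta[iv.chrom][lo:hi]))
    if n_dropped:
        logger.warning(
            "dropped %d region(s) whose ±%d bp window exceeded a chromosome end",
            n_dropped,
            half_window,
        )
    return seqs


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; any other symbol (N etc.) -> 4."""
    codes = np.full(len(seq), 4, dtype=np.int8)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    return codes


def _strand_scores(codes: np.ndarray, lut: np.ndarray) -> np.ndarray:
    w = lut.shape[1]
    n = len(codes) - w + 1
    scores = np.zeros(n)
    for j in range(w):
        scores += lut[codes[j : j + n], j]
    return scores


def scan_best_site(sequence: str, pwm: PWM) -> tuple[float, int, str]:
    """Best log-odds site of a PWM in a sequence, over both strands.

    Returns ``(score, start, strand)`` with ``start`` the 0-based offset of
    the site in the forward sequence.  Ambiguous bases score 0 (log-odds of
    an uninformative base).  Ties resolve to the smallest start, then to the
    + strand.
    """
    w = pwm.width
    if len(sequence) < w:
        raise ValueError(f"sequence length {len(sequence)} < motif width {w}")
    seq = sequence.upper()
    lut = np.vstack([pwm.log_odds(), np.zeros(w)])  # row 4: N scores 0
    fwd = _strand_scores(_encode(seq), lut)
    rc = seq.translate(_COMPLEMENT)[::-1]
    rev = _strand_scores(_encode(rc), lut)[::-1]  # rev[i]: site at fwd offset i
    # choose the best (score, then smaller start, then + strand)
    best = (-np.inf, len(seq), "-")
    fi = int(np.argmax(fwd))
    ri = int(np.argmax(rev))
    for score, pos, strand in ((fwd[fi], fi, "+"), (rev[ri], ri, "-")):
        # within a strand argmax already gives the smallest position
        if (score, -pos, strand == "+") > (best[0], -best[1], best[2] == "+"):
            best = (float(score), int(pos), strand)
    return best


@dataclass
class CentralEnrichment:
    """Centrality of one motif's best sites across a sequence set."""

    motif_id: str
    n_sequences: int
    n_passing: int
    central_hits: int
    p0: float
    p_value: float
    score_min: float
    no_passing_sequences: bool

    @property
    def central_fraction(self) -> float:
        return self.central_hits / self.n_passing if self.n_passing else 0.0


def central_enrichment(
    sequences: Sequence[str],
    pwm: PWM,
    central_half: int = 100,
    score_min: float | None = None,
) -> CentralEnrichment:
    """Binomial test for central concentration of best motif sites.

    Sequences whose best site scores below ``score_min`` (default 60% of
    the motif's maximum log-odds) are ignored; among the rest, sites fully
    inside the center ± central_half window count as hits, and the hit
    count is tested against Binomial(n, p0) with
    p0 = (2*central_half - W + 1) / (L - W + 1).
    """
    if not sequences:
        raise ValueError("no sequences supplied")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError("sequences must all have the same length")
    L = lengths.pop()
    w = pwm.width
    if not w <= 2 * central_half < L:
        raise ValueError("need motif width <= 2*central_half < sequence length")
    if score_min is None:
        score_min = 0.6 * pwm.max_score()

    center = L // 2
    lo, hi = center - central_half, center + central_half
    n_pass = 0
    hits = 0
    for seq in sequences:
        score, pos, _ = scan_best_site(seq, pwm)
        if score < score_min:
            continue
        n_pass += 1
        if pos >= lo and pos + w <= hi:
            hits += 1
    p0 = (2 * central_half - w + 1) / (L - w + 1)
    if n_pass == 0:
        return CentralEnrichment(
            pwm.motif_id, len(sequences), 0, 0, p0, 1.0, score_min, True
        )
    p = stats.binomtest(hits, n_pass, p0, alternative="greater").pvalue
    return CentralEnrichment(
        pwm.motif_id, len(sequences), n_pass, hits, p0, float(p), score_min, False
    )


def rank_motifs(
    sequences: Sequence[str],
    pwm_library: Sequence[PWM],
    central_half: int = 100,
    score_min_fraction: float = 0.6,
) -> pd.DataFrame:
    """Rank a PWM library by central enrichment p-value.

    Ties in p-value are broken by the larger central hit fraction, then by
    motif id for determinism.  Returns a report table sorted by rank.
    """
    if not pwm_library:
        raise ValueError("PWM library is empty")
    entries = [
        central_enrichment(
            sequences, pwm, central_half, score_min_fraction * pwm.max_score()
        )
        for pwm in pwm_library
    ]
    df = pd.DataFrame(
        {
            "motif_id": [e.motif_id for e in entries],
            "n_sequences": [e.n_sequences for e in entries],
            "n_passing": [e.n_passing for e in entries],
            "central_hits": [e.central_hits for e in entries],
            "central_fraction": [e.central_fraction for e in entries],
            "p0": [e.p0 for e in entries],
            "p_value": [e.p_value for e in entries],
        }
    )
    df = df.sort_values(
        by=["p_value", "central_fraction", "motif_id"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
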