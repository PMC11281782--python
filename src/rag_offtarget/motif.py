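"""Heptamer-anchored motif matrices and sequence-logo statistics.

Flanking sequences at signature breakpoints are extracted reading in the
heptamer direction and strand-normalized so every sequence starts with the
CAC of its motif hit.  The logo statistic is Shannon information content in
bits against a uniform 4-letter background (no small-sample correction by
default), so 0 <= IC <= 2 per position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._util import BASES, revcomp
from .io_formats import GenomeSequences
from .signature import MotifHit, Orientation

__all__ = [
    "MotifMatrix",
    "CanonicalRss",
    "extract_signal_flank",
    "build_motif_matrix",
    "consensus_and_similarity",
]


@dataclass(frozen=True)
class CanonicalRss:
    """The canonical recombination signal sequence constants."""

    heptamer: str = "CACAGTG"
    nonamer: str = "ACAAAAACC"
    spacer_lengths: tuple[int, int] = (12, 23)


@dataclass
class MotifMatrix:
    """Per-position base counts/probabilities with information content.

    ``counts`` and ``probs`` are (4, width) arrays in A,C,G,T row order;
    ``ic_bits[i] = 2 + sum_b probs[b,i] * log2(probs[b,i])`` with 0*log0 = 0.
    """

    width: int
    counts: np.ndarray
    probs: np.ndarray
    ic_bits: np.ndarray
    n_seqs: int


def extract_signal_flank(
    genome: GenomeSequences,
    chrom: str,
    pos: int,
    hit: MotifHit,
    width: int = 7,
) -> str | None:
    """``width`` bases from the motif's first base, reading heptamer-ward.

    GTG_LEFT hits are reverse complemented so every returned string reads
    CAC... left to right.  Returns None when the window would run past a
    contig end (such sequences are discarded, not padded).
    """
    seq = genome.contigs[chrom]
    if hit.orientation is Orientation.CAC_RIGHT:
        start = pos + hit.offset_bp
        end = start + width
        if end > len(seq):
            return None
        return seq[start:end]
    # GTG_LEFT: the motif's last top-strand base is at pos-1-offset; the
    # heptamer reads leftward from there.
    last = pos - 1 - hit.offset_bp
    start = last + 1 - width
    if start < 0:
        return None
    return revcomp(seq[start : last + 1])


def build_motif_matrix(
    seqs: Sequence[str], pseudocount: float = 0.0, small_sample_correction: bool = False
) -> MotifMatrix:
    """Count/probability matrix with per-position information content.

    probs = (counts + pseudocount) / (n + 4 * pseudocount) per column.  The
    optional small-sample correction subtracts the standard 3/(2*ln2*n) term
    from every position's IC (floored at 0).
    """
    if not seqs:
        raise ValueError("at least one sequence required")
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValueError("sequences must have equal lengths")
    base_index = {b: i for i, b in enumerate(BASES)}
    counts = np.zeros((4, width), dtype=float)
    for s in seqs:
        for i, b in enumerate(s):
            if b in base_index:  # N and gaps are ignored in the counts
                counts[base_index[b], i] += 1
    n = len(seqs)
    denom = counts.sum(axis=0) + 4.0 * pseudocount
    denom[denom == 0] = 1.0
    probs = (counts + pseudocount) / denom
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log2(probs), 0.0)
    ic = 2.0 + plogp.sum(axis=0)
    if small_sample_correction:
        ic = np.maximum(ic - 3.0 / (2.0 * math.log(2) * n), 0.0)
    return MotifMatrix(width=width, counts=counts, probs=probs, ic_bits=ic, n_seqs=n)


def consensus_and_similarity(
    matrix: MotifMatrix, canon: CanonicalRss | None = None
) -> tuple[str, np.ndarray, float]:
    """Consensus string and per-position match probability to the heptamer.

    Consensus is the argmax base per column, ties resolved to the
    alphabetically smallest base.  Match probability at position i is the
    probability mass on the canonical heptamer base; the mean is taken over
    the heptamer width.
    """
    canon = canon or CanonicalRss()
    if matrix.width < len(canon.heptamer):
        raise ValueError(
            f"matrix width {matrix.width} < heptamer length {len(canon.heptamer)}"
        )
    consensus = "".join(BASES[i] for i in matrix.probs.argmax(axis=0))
    base_index = {b: i for i, b in enumerate(BASES)}
    match = np.array(
        [matrix.probs[base_index[b], i] for i, b in enumerate(canon.heptamer)]
    )
    return consensus, match, float(match.mean())
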