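"""The RAG off-target signature screen.

An SV is called RAG-mediated when a CAC trinucleotide lies immediately 3' of
the breakpoint (or its reverse complement GTG immediately 5' of it) within a
configurable window — 21 bp by default — at *both* breakpoints.  Only the top
strand is scanned: a GTG to the left on the top strand is exactly the
reverse-complement heptamer case, so scanning the bottom strand as well would
double count every hit::

    5' ...NNN[CAC]AGTG... 3'     heptamer to the right of the break (CAC_RIGHT)
    5' ...CACT[GTG]NNN... 3'     heptamer to the left, on the other strand
                                 (GTG_LEFT; reads CACAGTG bottom-strand)

Both orientations are accepted at either breakpoint independently, and the
breakpoint base itself may be the first motif base (offset 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from ._util import revcomp
from .io_formats import GenomeSequences, SvRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureConfig",
    "Orientation",
    "MotifHit",
    "SizeCategory",
    "RagCallDecision",
    "subtract_control_svs",
    "find_motif_hits",
    "classify_rag_mediated",
    "recombinant_size",
]


class Orientation(str, Enum):
    CAC_RIGHT = "CAC_RIGHT"
    GTG_LEFT = "GTG_LEFT"


class SizeCategory(str, Enum):
    LT_1KB = "LT_1KB"
    KB_1_TO_10 = "KB_1_TO_10"
    GT_10KB = "GT_10KB"
    NA = "NA"


@dataclass
class SignatureConfig:
    """Parameters of the breakpoint signature screen.

    window_bp
        Maximum breakpoint-to-motif distance; distances 0..window_bp inclusive
        pass ("within 21 bp" read permissively).
    motif
        Trinucleotide scanned 3' of the break; its reverse complement is
        scanned 5'.
    require_both_breakpoints
        When true (default) both breakpoints must carry a hit.
    subtraction_slop_bp
        Positional tolerance when matching tumor SVs against control SVs.
    """

    window_bp: int = 21
    motif: str = "CAC"
    require_both_breakpoints: bool = True
    subtraction_slop_bp: int = 50

    def __post_init__(self) -> None:
        if self.window_bp < 0:
            raise ValueError("window_bp must be >= 0")
        if len(self.motif) != 3 or set(self.motif) - set("ACGT"):
            raise ValueError("motif must be a trinucleotide over ACGT")


@dataclass
class MotifHit:
    offset_bp: int
    orientation: Orientation
    matched_seq: str


@dataclass
class RagCallDecision:
    sv: SvRecord
    is_rag_mediated: bool
    hits_bp1: list[MotifHit] = field(default_factory=list)
    hits_bp2: list[MotifHit] = field(default_factory=list)
    size_bp: int | None = None
    size_category: SizeCategory = SizeCategory.NA


def subtract_control_svs(
    tumor: Sequence[SvRecord],
    control: Sequence[SvRecord],
    slop: int = 50,
) -> list[SvRecord]:
    """Remove tumor SVs matched by a control (kidney/tail-style) SV.

    A tumor SV is removed iff some control SV has the same sv_type, the same
    contig pair, and both break positions within ``slop`` bp.  Order of the
    surviving records is preserved.
    """
    if slop < 0:
        raise ValueError("slop must be >= 0")
    by_key: dict[tuple[str, str, str], list[SvRecord]] = {}
    for c in control:
        by_key.setdefault((c.sv_type, c.chrom1, c.chrom2), []).append(c)
    kept = []
    for t in tumor:
        matches = by_key.get((t.sv_type, t.chrom1, t.chrom2), ())
        if any(
            abs(t.pos1 - c.pos1) <= slop and abs(t.pos2 - c.pos2) <= slop
            for c in matches
        ):
            continue
        kept.append(t)
    return kept


def find_motif_hits(
    genome: GenomeSequences,
    chrom: str,
    pos: int,
    cfg: SignatureConfig | None = None,
) -> list[MotifHit]:
    """Scan both motif orientations around a breakpoint on the top strand.

    CAC_RIGHT hits have the motif's first base in [pos, pos + window_bp];
    GTG_LEFT hits have the motif's last base in [pos - window_bp, pos - 1],
    with offset measured to the nearest motif base in both cases.  Windows
    running past a contig end are truncated (logged, not an error).  Hits are
    returned sorted by offset, CAC_RIGHT first on ties.
    """
    cfg = cfg or SignatureConfig()
    seq = genome.contigs[chrom]
    if not 0 <= pos <= len(seq):
        raise ValueError(f"breakpoint {chrom}:{pos} outside contig bounds")
    right_motif = cfg.motif
    left_motif = revcomp(cfg.motif)
    w = cfg.window_bp
    hits: list[MotifHit] = []
    hi = min(pos + w, len(seq) - 3)
    if pos + w > len(seq) - 3:
        logger.debug("window at %s:%d truncated at contig end", chrom, pos)
    for start in range(pos, hi + 1):
        if seq[start : start + 3] == right_motif:
            hits.append(MotifHit(start - pos, Orientation.CAC_RIGHT, right_motif))
    # last base of the left-motif trinucleotide ranges over [pos-w, pos-1]
    lo = max(pos - w, 2)
    for last in range(lo, pos):
        if seq[last - 2 : last + 1] == left_motif:
            hits.append(MotifHit(pos - 1 - last, Orientation.GTG_LEFT, left_motif))
    hits.sort(key=lambda h: (h.offset_bp, h.orientation != Orientation.CAC_RIGHT))
    return hits


def recombinant_size(sv: SvRecord) -> tuple[int | None, SizeCategory]:
    """DNA fragment size spanning the two breakpoints, binned into three ranges.

    <1000 -> LT_1KB, 1000..10000 inclusive -> KB_1_TO_10, >10000 -> GT_10KB;
    inter-chromosomal events have no size (NA).
    """
    if sv.chrom1 != sv.chrom2:
        return None, SizeCategory.NA
    size = sv.pos2 - sv.pos1
    if size < 1000:
        return size, SizeCategory.LT_1KB
    if size <= 10000:
        return size, SizeCategory.KB_1_TO_10
    return size, SizeCategory.GT_10KB


def classify_rag_mediated(
    sv: SvRecord,
    genome: GenomeSequences,
    cfg: SignatureConfig | None = None,
) -> RagCallDecision:
    """Apply the two-criterion screen to one SV and attach the evidence."""
    cfg = cfg or SignatureConfig()
    hits1 = find_motif_hits(genome, sv.chrom1, sv.pos1, cfg)
    hits2 = find_motif_hits(genome, sv.chrom2, sv.pos2, cfg)
    if cfg.require_both_breakpoints:
        is_rag = bool(hits1) and bool(hits2)
    else:
        is_rag = bool(hits1) or bool(hits2)
    size_bp, size_cat = recombinant_size(sv)
    return RagCallDecision(
        sv=sv,
        is_rag_mediated=is_rag,
        hits_bp1=hits1,
        hits_bp2=hits2,
        size_bp=size_bp,
        size_category=size_cat,
    )
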