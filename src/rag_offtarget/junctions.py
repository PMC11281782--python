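"""Junction sequence analysis: P/N partitioning and joint-type classification.

A junction record carries the joined sequence together with the two reference
flanks at the recorded breakpoints, all read in junction orientation: the
left flank ends at breakpoint 1 (read toward the join) and the right flank
begins at breakpoint 2 (read away from the join).  The partition decomposes
the junction as

    [left-flank match][P_left][N][P_right][right-flank match]

where each P segment is the reverse complement of the adjacent retained flank
terminus (hairpin-opening chemistry) and N is the non-templated middle (TdT
additions).  Chew-back is the number of flank bases adjacent to the recorded
breakpoints that are absent from the junction.

Conventions (documented, configurable where noted): microhomology — bases
claimed by both maximal flank matches — is assigned to the left match; P
segments are called greedily, maximal on the left then on the right, capped
at 10 nt by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from ._util import revcomp, round_half_away
from .io_formats import GenomeSequences, SvRecord
from .signature import MotifHit, Orientation, SignatureConfig, find_motif_hits

__all__ = [
    "JunctionRecord",
    "PNPartition",
    "JointKind",
    "JointType",
    "partition_junction",
    "call_pn_segments",
    "classify_joint",
    "cohort_junction_stats",
    "recover_chemistry_means",
    "junction_record_from_sv",
]

DEFAULT_P_MAX = 10


@dataclass
class JunctionRecord:
    sv_id: str
    junction_seq: str
    left_flank: str
    right_flank: str

    def reverse_complemented(self) -> "JunctionRecord":
        """The same join read from the other side (flanks swapped)."""
        return JunctionRecord(
            sv_id=self.sv_id,
            junction_seq=revcomp(self.junction_seq),
            left_flank=revcomp(self.right_flank),
            right_flank=revcomp(self.left_flank),
        )


@dataclass
class PNPartition:
    left_match_len: int
    right_match_len: int
    insert_seq: str
    p_left_len: int
    p_right_len: int
    n_len: int
    del_left: int
    del_right: int
    microhomology_len: int


class JointKind(str, Enum):
    SIGNAL = "SIGNAL"
    CODING = "CODING"
    HYBRID = "HYBRID"


@dataclass
class JointType:
    value: JointKind
    signal_end_1: bool
    signal_end_2: bool
    low_confidence: bool = False


def _lcp(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def _max_palindrome_prefix(insert: str, retained_left: str, cap: int) -> int:
    """Longest insert prefix equal to revcomp of the retained left terminus."""
    best = 0
    limit = min(cap, len(insert), len(retained_left))
    for p in range(1, limit + 1):
        if insert[:p] == revcomp(retained_left[-p:]):
            best = p
    return best


def call_pn_segments(
    insert: str,
    retained_left: str,
    retained_right: str,
    p_max: int = DEFAULT_P_MAX,
) -> tuple[int, int, int]:
    """Split an insert into (p_left, p_right, n) — greedy left then right.

    p_left is the maximal insert prefix matching the reverse complement of
    the retained left-flank terminus (capped at ``p_max``); p_right is then
    the maximal suffix matching the reverse complement of the retained
    right-flank start, within the remaining insert; n is the middle.
    """
    p_left = _max_palindrome_prefix(insert, retained_left, p_max)
    rest = insert[p_left:]
    p_right = 0
    limit = min(p_max, len(rest), len(retained_right))
    for p in range(1, limit + 1):
        if rest[-p:] == revcomp(retained_right[:p]):
            p_right = p
    n = len(insert) - p_left - p_right
    return p_left, p_right, n


def partition_junction(
    rec: JunctionRecord, p_max: int = DEFAULT_P_MAX
) -> PNPartition:
    """Decompose a junction into flank matches, P, N and chew-back lengths.

    The raw flank matches are the longest junction prefix equal to the left
    flank and the longest junction suffix equal to the right flank; when they
    overlap, the overlap is microhomology and is assigned to the left match.
    Chew-back is measured from the raw matches, so it is symmetric under
    reverse complementation of the record.
    """
    jx = rec.junction_seq
    if len(jx) < 1:
        raise ValueError("junction sequence must be non-empty")
    raw_l = _lcp(jx, rec.left_flank)
    raw_r = _lcp(jx[::-1], rec.right_flank[::-1])
    if raw_l + raw_r <= len(jx):
        left_match, right_match, micro = raw_l, raw_r, 0
    else:
        micro = raw_l + raw_r - len(jx)
        left_match = raw_l
        right_match = len(jx) - raw_l
    insert = jx[left_match : len(jx) - right_match]
    retained_left = rec.left_flank[:raw_l]
    retained_right = rec.right_flank[len(rec.right_flank) - raw_r :]
    p_left, p_right, n = call_pn_segments(insert, retained_left, retained_right, p_max)
    return PNPartition(
        left_match_len=left_match,
        right_match_len=right_match,
        insert_seq=insert,
        p_left_len=p_left,
        p_right_len=p_right,
        n_len=n,
        del_left=len(rec.left_flank) - raw_l,
        del_right=len(rec.right_flank) - raw_r,
        microhomology_len=micro,
    )


def junction_record_from_sv(
    sv: SvRecord, genome: GenomeSequences, flank: int = 50
) -> JunctionRecord:
    """Build the reference flanks for an SV's junction in join orientation.

    The retained side of each break is read toward/away from the join; a
    retained-right side at breakpoint 1 or retained-left side at breakpoint 2
    (inversion-type ends) is reverse complemented so both flanks read in
    junction orientation.
    """
    if sv.strand1 == "+":
        left = genome.fetch(sv.chrom1, max(0, sv.pos1 - flank), sv.pos1)
    else:
        end = min(genome.length(sv.chrom1), sv.pos1 + flank)
        left = revcomp(genome.fetch(sv.chrom1, sv.pos1, end))
    if sv.strand2 == "-":
        end = min(genome.length(sv.chrom2), sv.pos2 + flank)
        right = genome.fetch(sv.chrom2, sv.pos2, end)
    else:
        right = revcomp(genome.fetch(sv.chrom2, max(0, sv.pos2 - flank), sv.pos2))
    return JunctionRecord(
        sv_id=sv.sv_id,
        junction_seq=sv.junction_seq or "",
        left_flank=left,
        right_flank=right,
    )


def _signal_end(
    genome: GenomeSequences,
    chrom: str,
    pos: int,
    retained: str,
    signal_offset_max: int,
) -> bool:
    """True when the heptamer CAC abuts the junction on the retained side.

    A left-retained end (strand ``+``) carries its heptamer reading leftward
    from the break (GTG_LEFT on the top strand); a right-retained end
    (strand ``-``) carries it reading rightward (CAC_RIGHT).
    """
    # GTG_LEFT offsets are measured from pos-1, so a window of
    # signal_offset_max + 1 is needed to expose offset 0 on the left side
    cfg = SignatureConfig(window_bp=signal_offset_max + 1)
    want = Orientation.GTG_LEFT if retained == "+" else Orientation.CAC_RIGHT
    return any(
        h.orientation is want and h.offset_bp <= signal_offset_max
        for h in find_motif_hits(genome, chrom, pos, cfg)
    )


def classify_joint(
    sv: SvRecord,
    rec: JunctionRecord | None,
    genome: GenomeSequences,
    signal_offset_max: int = 0,
) -> JointType:
    """Call the joint SIGNAL, CODING, or HYBRID from per-end signal evidence.

    An end is a signal end iff the motif sits within ``signal_offset_max`` bp
    of the junction point on the retained side (default 0: the heptamer abuts
    the junction).  SIGNAL if both ends, CODING if neither, HYBRID if exactly
    one.  With no junction sequence available the call is made from reference
    flanks alone and flagged low-confidence.
    """
    s1 = _signal_end(genome, sv.chrom1, sv.pos1, sv.strand1, signal_offset_max)
    s2 = _signal_end(genome, sv.chrom2, sv.pos2, sv.strand2, signal_offset_max)
    if s1 and s2:
        kind = JointKind.SIGNAL
    elif s1 or s2:
        kind = JointKind.HYBRID
    else:
        kind = JointKind.CODING
    low_conf = rec is None or not rec.junction_seq
    return JointType(kind, s1, s2, low_confidence=low_conf)


def recover_chemistry_means(
    partitions: Sequence[PNPartition],
    records: Sequence[JunctionRecord],
    p_max: int = DEFAULT_P_MAX,
) -> dict[str, float]:
    """Moment-corrected cohort estimates of mean chew-back, P and N length.

    Maximal matching systematically misassigns chance-matching bases: the
    flank match overshoots the true chew boundary, and the P call absorbs
    insert bases that happen to extend the palindrome.  Under an i.i.d.
    flanking-base model with chance match probability ``m`` (estimated from
    the flank composition as sum of squared base frequencies), the overshoot
    per boundary is geometric, giving the exact identity

        E[overshoot] = g * P(apparent chew >= 1),   g = m / (1 - m)

    and analogous first-order corrections for P over-claims and the N
    remainder.  Returns a dict with ``mean_chew`` (per end), ``mean_p``
    (per uncut end, i.e. conditional on the hairpin-opening opportunity) and
    ``mean_n`` (per junction).
    """
    if not partitions:
        raise ValueError("no partitions to summarize")
    comp: dict[str, int] = {}
    for rec in records:
        for b in rec.left_flank + rec.right_flank:
            comp[b] = comp.get(b, 0) + 1
    total = sum(comp.values())
    m = sum((c / total) ** 2 for c in comp.values())
    g = m / (1.0 - m)

    import numpy as np

    dels = np.array([[p.del_left, p.del_right] for p in partitions]).ravel()
    ps = np.array([[p.p_left_len, p.p_right_len] for p in partitions]).ravel()
    ns = np.array([p.n_len for p in partitions], dtype=float)
    inserts = np.array([len(p.insert_seq) for p in partitions], dtype=float)

    mean_chew = float(dels.mean() + g * (dels >= 1).mean())
    # P over-claim happens when the palindrome extension stops on a mismatch,
    # i.e. the cap was not hit and unclaimed N bases remained
    n_per_end = np.repeat(ns, 2)
    p_overclaim = g * float(((ps < p_max) & (n_per_end > 0)).mean())
    p_per_end = float(ps.mean()) - p_overclaim
    # fraction of truly uncut ends: apparent-zero ends minus fully-overshot ones
    s_hat = g * float((dels == 1).mean())
    f_uncut = max(float((dels == 0).mean()) - s_hat, 1e-9)
    mean_p = p_per_end / f_uncut
    # N = corrected insert mass minus corrected total P mass
    insert_corr = float(inserts.mean()) + 2.0 * g * float((dels >= 1).mean())
    mean_n = insert_corr - 2.0 * p_per_end
    return {
        "mean_chew": mean_chew,
        "mean_p": mean_p,
        "mean_n": mean_n,
        "match_prob": float(m),
    }


def cohort_junction_stats(
    records: Sequence[tuple[PNPartition, JointType]],
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-group junction chemistry summary.

    P-frequency = fraction of junctions with any P bases; N-frequency =
    fraction with n_len > 0; hybrid percentage = 100 x hybrid / total.  P and
    N length summaries (mean/median/max) are computed over junctions where
    the segment is present; the junction P length is p_left + p_right.
    Empty groups are omitted.
    """
    if groups is None:
        groups = ["all"] * len(records)
    df = pd.DataFrame(
        {
            "group": list(groups),
            "p_len": [p.p_left_len + p.p_right_len for p, _ in records],
            "n_len": [p.n_len for p, _ in records],
            "hybrid": [jt.value is JointKind.HYBRID for _, jt in records],
        }
    )
    rows = []
    for group, sub in df.groupby("group", sort=True):
        n = len(sub)
        if n == 0:
            continue
        with_p = sub.loc[sub.p_len > 0, "p_len"]
        with_n = sub.loc[sub.n_len > 0, "n_len"]
        rows.append(
            {
                "group": group,
                "n_junctions": n,
                "p_frequency_pct": round_half_away(100.0 * len(with_p) / n, 1),
                "n_frequency_pct": round_half_away(100.0 * len(with_n) / n, 1),
                "p_len_mean": round_half_away(with_p.mean(), 1) if len(with_p) else 0.0,
                "p_len_median": float(with_p.median()) if len(with_p) else 0.0,
                "p_len_max": int(with_p.max()) if len(with_p) else 0,
                "n_len_mean": round_half_away(with_n.mean(), 1) if len(with_n) else 0.0,
                "n_len_median": float(with_n.median()) if len(with_n) else 0.0,
                "n_len_max": int(with_n.max()) if len(with_n) else 0,
                "hybrid_pct": round_half_away(100.0 * sub.hybrid.sum() / n, 1),
            }
        )
    return pd.DataFrame(rows)
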