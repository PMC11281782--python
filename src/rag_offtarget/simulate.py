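"""Synthetic cohorts: a toy genome with planted RSS/cRSS sites and
RAG-style rearrangements with realistic junction chemistry.

The generator emulates what the screen assumes about real data: recombination
signal sequences (heptamer + 12/23 spacer + nonamer) and degenerate cryptic
heptamers planted on either strand; RAG events that cut at planted sites and
join with chew-back (shifted geometric), hairpin-opening P additions (uniform,
only at uncut coding ends) and TdT N additions (Poisson); motif-free
background SVs; and germline SVs shared between tumor and matched control.
Every event is recorded in a truth table from which each junction sequence is
exactly re-derivable given the reference.

Breakpoints are emitted at the enzymatic cut positions; chew-back lives in
the junction sequence only.  Optional jitter emulates caller imprecision and
is applied toward the side that a real aligner would drift (away from the
planted heptamer), so detection degrades gracefully as jitter approaches the
scan window.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import revcomp
from .io_formats import (
    GenomeSequences,
    SvRecord,
    TranscriptModel,
    write_bedpe,
    write_fasta,
    write_gff3,
)
from .motif import CanonicalRss

__all__ = [
    "SimConfig",
    "PlantedSite",
    "PlantedEvent",
    "SimResult",
    "generate_genome",
    "plant_sites",
    "simulate_events",
    "simulate_junctions",
    "simulate",
    "emit",
]

_CANON = CanonicalRss()


@dataclass
class SimConfig:
    """Study conditions for one simulated sample.

    Junction-chemistry defaults mirror the reported junction features: P
    segments up to 9 nt, mean N length 5, and a joint-type mixture dominated
    by hybrid joints as observed for core-RAG leukemic cells.
    """

    genome_length: int = 300_000
    n_contigs: int = 3
    gc_fraction: float = 0.42
    n_genes: int = 10
    n_census_genes: int = 5
    n_rss_pairs: int = 5
    n_crss: int = 120
    crss_mutation_rate: float = 0.3
    n_rag_events: int = 10
    n_background_svs: int = 10
    n_germline_svs: int = 20
    joint_type_probs: tuple[float, float, float] = (0.1, 0.2, 0.7)
    chew_geom_p: float = 0.2
    chew_max_bp: int = 20
    p_open_max: int = 9
    n_len_poisson_lambda: float = 5.0
    breakpoint_jitter_bp: int = 0
    germline_jitter_bp: int = 0
    tra_fraction: float = 0.15
    anchor_bp: int = 50
    margin_bp: int = 200
    sample_id: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.joint_type_probs) - 1.0) > 1e-9:
            raise ValueError("joint_type_probs must sum to 1")
        if not 0 < self.chew_geom_p <= 1:
            raise ValueError("chew_geom_p must be in (0, 1]")
        for name in (
            "n_rss_pairs",
            "n_crss",
            "n_rag_events",
            "n_background_svs",
            "n_germline_svs",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class PlantedSite:
    site_id: str
    kind: str  # "RSS" or "CRSS"
    chrom: str
    start: int  # first base of the planted block (top strand)
    orient: str  # "+": heptamer reads rightward; "-": planted as revcomp
    seq: str  # planted top-strand sequence
    breakpoint: int  # cut position: heptamer-proximal edge
    spacer: int | None = None  # RSS only
    pair_id: str | None = None  # RSS only


@dataclass
class PlantedEvent:
    event_id: str
    mechanism: str  # RAG / BACKGROUND / GERMLINE
    sv: SvRecord
    joint_type: str | None = None
    true_pos1: int = -1
    true_pos2: int = -1
    site1: str | None = None
    site2: str | None = None
    chew_left: int = 0
    chew_right: int = 0
    p_left: int = 0
    p_right: int = 0
    n_len: int = 0
    n_seq: str = ""
    junction_seq: str | None = None
    genes: list[str] = field(default_factory=list)
    census_hit: bool = False


@dataclass
class SimResult:
    cfg: SimConfig
    genome: GenomeSequences
    models: list[TranscriptModel]
    sites: list[PlantedSite]
    events: list[PlantedEvent]
    tumor: list[SvRecord]
    control: list[SvRecord]
    census: set[str]


# ---------------------------------------------------------------------------


def generate_genome(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GenomeSequences, list[TranscriptModel]]:
    """I.i.d. random contigs at the configured GC plus tiled toy gene models.

    Genes are spaced evenly across contigs (round robin), each with three
    exons, a 100 bp 5'UTR, a 150 bp 3'UTR and random strand.
    """
    if cfg.genome_length < 10_000:
        raise ValueError("genome_length must be >= 10 kb")
    rng = rng or np.random.default_rng(cfg.seed)
    gc = cfg.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    contig_len = cfg.genome_length // cfg.n_contigs
    contigs = {}
    for i in range(cfg.n_contigs):
        arr = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=contig_len, p=probs)
        contigs[f"chr{i + 1}"] = arr.tobytes().decode("ascii")
    genome = GenomeSequences(contigs)

    models = []
    names = list(contigs)
    per_contig = [cfg.n_genes // cfg.n_contigs] * cfg.n_contigs
    for i in range(cfg.n_genes % cfg.n_contigs):
        per_contig[i] += 1
    gi = 0
    for ci, chrom in enumerate(names):
        k = per_contig[ci]
        if k == 0:
            continue
        slot = contig_len // k
        for j in range(k):
            base = j * slot + max(cfg.margin_bp, 2500)
            exon_sizes = rng.integers(200, 400, size=3)
            intron_sizes = rng.integers(500, 1500, size=2)
            exons = []
            pos = base
            for e in range(3):
                exons.append((pos, pos + int(exon_sizes[e])))
                pos = exons[-1][1] + (int(intron_sizes[e]) if e < 2 else 0)
            start = exons[0][0]
            strand = "+" if rng.random() < 0.5 else "-"
            cds = [(exons[0][0] + 100, exons[0][1]), exons[1], (exons[2][0], exons[2][1] - 150)]
            gene = f"G{gi:03d}"
            models.append(
                TranscriptModel(
                    transcript_id=f"{gene}.t1",
                    gene=gene,
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=exons[-1][1],
                    exons=exons,
                    cds=cds,
                )
            )
            gi += 1
    return genome, models


def _mutate_tail(heptamer: str, rate: float, rng: np.random.Generator) -> str:
    """Mutate heptamer positions 4-7 independently (uniform base redraw)."""
    tail = list(heptamer[3:])
    for i in range(len(tail)):
        if rng.random() < rate:
            tail[i] = "ACGT"[rng.integers(0, 4)]
    return heptamer[:3] + "".join(tail)


def plant_sites(
    genome: GenomeSequences,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenomeSequences, list[PlantedSite]]:
    """Overwrite genome bases with non-overlapping RSS and cRSS sites.

    RSS pairs are planted as heptamer + spacer + nonamer with 12/23 spacer
    pairing; cRSSs are bare heptamers whose positions 4-7 mutate at
    ``crss_mutation_rate`` (CAC fixed).  Each site carries a random strand
    orientation; minus-strand sites are planted as the reverse complement so
    the heptamer reads leftward on the top strand.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    arrays = {c: bytearray(s, "ascii") for c, s in genome.contigs.items()}
    names = list(arrays)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in names}
    sites: list[PlantedSite] = []

    def free(chrom: str, start: int, end: int) -> bool:
        if start < cfg.margin_bp or end > len(arrays[chrom]) - cfg.margin_bp:
            return False
        return all(e <= start - 30 or s >= end + 30 for s, e in occupied[chrom])

    def place(length: int) -> tuple[str, int]:
        for _ in range(10_000):
            chrom = names[rng.integers(0, len(names))]
            start = int(rng.integers(cfg.margin_bp, len(arrays[chrom]) - cfg.margin_bp - length))
            if free(chrom, start, start + length):
                occupied[chrom].append((start, start + length))
                return chrom, start
        raise ValueError("genome too small for requested number of sites")

    def write_block(chrom: str, start: int, block: str, orient: str) -> str:
        top = block if orient == "+" else revcomp(block)
        arrays[chrom][start : start + len(block)] = top.encode("ascii")
        return top

    sid = 0
    for pair in range(cfg.n_rss_pairs):
        pair_id = f"rsspair{pair}"
        for spacer_len in _CANON.spacer_lengths:
            spacer = "".join("ACGT"[rng.integers(0, 4)] for _ in range(spacer_len))
            block = _CANON.heptamer + spacer + _CANON.nonamer
            orient = "+" if rng.random() < 0.5 else "-"
            chrom, start = place(len(block))
            top = write_block(chrom, start, block, orient)
            bp = start if orient == "+" else start + len(block)
            # cut at the heptamer-proximal edge of the planted block
            if orient == "-":
                bp = start + len(block)
            sites.append(
                PlantedSite(
                    site_id=f"s{sid}",
                    kind="RSS",
                    chrom=chrom,
                    start=start,
                    orient=orient,
                    seq=top,
                    breakpoint=bp,
                    spacer=spacer_len,
                    pair_id=pair_id,
                )
            )
            sid += 1
    for _ in range(cfg.n_crss):
        block = _mutate_tail(_CANON.heptamer, cfg.crss_mutation_rate, rng)
        orient = "+" if rng.random() < 0.5 else "-"
        chrom, start = place(len(block))
        top = write_block(chrom, start, block, orient)
        bp = start if orient == "+" else start + len(block)
        sites.append(
            PlantedSite(
                site_id=f"s{sid}",
                kind="CRSS",
                chrom=chrom,
                start=start,
                orient=orient,
                seq=top,
                breakpoint=bp,
            )
        )
        sid += 1
    planted = GenomeSequences({c: a.decode("ascii") for c, a in arrays.items()})
    return planted, sites


# ---------------------------------------------------------------------------


def _draw_chew(cfg: SimConfig, rng: np.random.Generator) -> int:
    # shifted geometric: support {0, 1, ...}, mean (1-p)/p, capped
    return min(int(rng.geometric(cfg.chew_geom_p)) - 1, cfg.chew_max_bp)


def _rand_bases(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[rng.integers(0, 4)] for _ in range(n))


def _build_junction(
    genome: GenomeSequences,
    chrom1: str,
    pos1: int,
    chrom2: str,
    pos2: int,
    chew_l: int,
    chew_r: int,
    p_l: int,
    p_r: int,
    n_seq: str,
    anchor: int,
) -> str:
    left = genome.fetch(chrom1, pos1 - anchor, pos1)
    right = genome.fetch(chrom2, pos2, pos2 + anchor)
    retained_left = left[: anchor - chew_l] if chew_l else left
    retained_right = right[chew_r:]
    p_left_seq = revcomp(retained_left[-p_l:]) if p_l else ""
    p_right_seq = revcomp(retained_right[:p_r]) if p_r else ""
    return retained_left + p_left_seq + n_seq + p_right_seq + retained_right


def simulate_events(
    genome: GenomeSequences,
    sites: Sequence[PlantedSite],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    models: Sequence[TranscriptModel] = (),
    census: set[str] | None = None,
) -> tuple[list[PlantedEvent], list[SvRecord], list[SvRecord]]:
    """Draw RAG, background and germline events; return (truth, tumor, control).

    RAG events pick two unused planted sites whose orientations realize the
    drawn joint type (a signal end keeps its heptamer against the junction, a
    coding end loses it), cut at the heptamer-proximal edges and join with
    drawn chew/P/N chemistry.  All RAG events use deletion-type retained
    sides (strand1 '+', strand2 '-'); a ``tra_fraction`` of them are
    inter-chromosomal.  Background and germline SVs draw breakpoints
    uniformly with no motif constraint; germline SVs appear in both call
    sets.
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    census = census or set()
    gene_spans = [(m.chrom, m.start, m.end, m.gene) for m in models]

    def genes_at(chrom: str, pos: int) -> list[str]:
        return [g for c, s, e, g in gene_spans if c == chrom and s <= pos < e]

    # End-1 of a deletion-type join retains the left side: a signal end there
    # needs a '-' site (heptamer reading leftward, retained); a coding end
    # needs a '+' site (heptamer to the right, lost).  End 2 is the mirror.
    pool = {"+": [s for s in sites if s.orient == "+"], "-": [s for s in sites if s.orient == "-"]}
    for key in pool:
        order = rng.permutation(len(pool[key]))
        pool[key] = [pool[key][i] for i in order]
    used: set[str] = set()

    def take(orient: str, predicate) -> PlantedSite | None:
        for s in pool[orient]:
            if s.site_id not in used and predicate(s):
                used.add(s.site_id)
                return s
        return None

    events: list[PlantedEvent] = []
    tumor: list[SvRecord] = []
    control: list[SvRecord] = []

    joint_kinds = ["SIGNAL", "CODING", "HYBRID"]
    anchor = cfg.anchor_bp
    i = 0
    attempts = 0
    max_attempts = 50 * max(1, cfg.n_rag_events)
    while i < cfg.n_rag_events and attempts < max_attempts:
        attempts += 1
        kind = joint_kinds[int(rng.choice(3, p=list(cfg.joint_type_probs)))]
        if kind == "SIGNAL":
            need1, need2 = "-", "+"
        elif kind == "CODING":
            need1, need2 = "+", "-"
        else:
            need1, need2 = ("-", "-") if rng.random() < 0.5 else ("+", "+")
        want_tra = rng.random() < cfg.tra_fraction

        # A coding end must not spuriously present the signal motif at the
        # junction point (possible by chance in the flanking sequence); such
        # sites are skipped so every planted joint type is recoverable.
        def ok_end1(s: PlantedSite) -> bool:
            if s.orient == "-":
                return True  # signal end: heptamer is planted
            b = s.breakpoint
            return genome.fetch(s.chrom, max(0, b - 3), b) != "GTG"

        def ok_end2(s: PlantedSite) -> bool:
            if s.orient == "+":
                return True
            b = s.breakpoint
            return genome.fetch(s.chrom, b, min(genome.length(s.chrom), b + 3)) != "CAC"

        site1 = take(need1, ok_end1)
        if site1 is None:
            break
        if want_tra:
            site2 = take(need2, lambda s: s.chrom > site1.chrom and ok_end2(s))
            if site2 is None:
                site2 = take(need2, lambda s: s.chrom != site1.chrom and ok_end2(s))
                if site2 is not None and site2.chrom < site1.chrom:
                    # keep end roles aligned with genomic order: re-pick end1
                    # on the smaller chromosome instead of swapping roles
                    used.discard(site2.site_id)
                    site2 = None
        else:
            site2 = take(
                need2,
                lambda s: s.chrom == site1.chrom
                and s.breakpoint > site1.breakpoint + 2 * anchor
                and ok_end2(s),
            )
        if site2 is None:
            used.discard(site1.site_id)
            continue
        s_left, s_right = site1, site2
        sig1 = s_left.orient == "-"
        sig2 = s_right.orient == "+"
        true_kind = (
            "SIGNAL" if sig1 and sig2 else "CODING" if not sig1 and not sig2 else "HYBRID"
        )
        pos1, pos2 = s_left.breakpoint, s_right.breakpoint
        chew_l = 0 if sig1 else _draw_chew(cfg, rng)
        chew_r = 0 if sig2 else _draw_chew(cfg, rng)
        p_l = int(rng.integers(0, cfg.p_open_max + 1)) if (not sig1 and chew_l == 0) else 0
        p_r = int(rng.integers(0, cfg.p_open_max + 1)) if (not sig2 and chew_r == 0) else 0
        n_len = int(rng.poisson(cfg.n_len_poisson_lambda)) if not (sig1 and sig2) else 0
        n_seq = _rand_bases(n_len, rng)
        junction = _build_junction(
            genome, s_left.chrom, pos1, s_right.chrom, pos2,
            chew_l, chew_r, p_l, p_r, n_seq, anchor,
        )
        # caller jitter drifts away from the planted heptamer so the motif
        # stays on the scanned side of the emitted breakpoint
        j1 = int(rng.integers(0, cfg.breakpoint_jitter_bp + 1)) if cfg.breakpoint_jitter_bp else 0
        j2 = int(rng.integers(0, cfg.breakpoint_jitter_bp + 1)) if cfg.breakpoint_jitter_bp else 0
        emit1 = pos1 + j1 if s_left.orient == "-" else pos1 - j1
        emit2 = pos2 - j2 if s_right.orient == "+" else pos2 + j2
        sv_type = "TRA" if s_left.chrom != s_right.chrom else "DEL"
        event_id = f"rag{i}"
        sv = SvRecord(
            sample_id=cfg.sample_id,
            chrom1=s_left.chrom,
            pos1=emit1,
            strand1="+",
            chrom2=s_right.chrom,
            pos2=emit2,
            strand2="-",
            sv_type=sv_type,
            sv_id=event_id,
            junction_seq=junction,
        ).canonical()
        genes = sorted(set(genes_at(s_left.chrom, pos1) + genes_at(s_right.chrom, pos2)))
        events.append(
            PlantedEvent(
                event_id=event_id,
                mechanism="RAG",
                sv=sv,
                joint_type=true_kind,
                true_pos1=pos1,
                true_pos2=pos2,
                site1=s_left.site_id,
                site2=s_right.site_id,
                chew_left=chew_l,
                chew_right=chew_r,
                p_left=p_l,
                p_right=p_r,
                n_len=n_len,
                n_seq=n_seq,
                junction_seq=junction,
                genes=genes,
                census_hit=bool(set(genes) & census),
            )
        )
        tumor.append(sv)
        i += 1

    def random_sv(prefix: str, i: int) -> tuple[SvRecord, PlantedEvent]:
        names = list(genome.contigs)
        if rng.random() < cfg.tra_fraction:
            c1, c2 = rng.choice(len(names), size=2, replace=False)
            chrom1, chrom2 = names[int(c1)], names[int(c2)]
            p1 = int(rng.integers(cfg.margin_bp, genome.length(chrom1) - cfg.margin_bp))
            p2 = int(rng.integers(cfg.margin_bp, genome.length(chrom2) - cfg.margin_bp))
            sv_type, strands = "TRA", ("+", "-")
        else:
            chrom1 = chrom2 = names[int(rng.integers(0, len(names)))]
            max_len = min(50_000, genome.length(chrom1) - 2 * cfg.margin_bp - 1)
            length = int(rng.integers(200, max_len))
            p1 = int(
                rng.integers(cfg.margin_bp, genome.length(chrom1) - cfg.margin_bp - length)
            )
            p2 = p1 + length
            sv_type = ["DEL", "INV", "DUP"][int(rng.integers(0, 3))]
            strands = {"DEL": ("+", "-"), "DUP": ("-", "+"), "INV": ("+", "+")}[sv_type]
        eid = f"{prefix}{i}"
        sv = SvRecord(
            sample_id=cfg.sample_id,
            chrom1=chrom1,
            pos1=p1,
            strand1=strands[0],
            chrom2=chrom2,
            pos2=p2,
            strand2=strands[1],
            sv_type=sv_type,
            sv_id=eid,
        ).canonical()
        genes = sorted(set(genes_at(chrom1, p1) + genes_at(chrom2, p2)))
        ev = PlantedEvent(
            event_id=eid,
            mechanism="BACKGROUND" if prefix == "bg" else "GERMLINE",
            sv=sv,
            true_pos1=sv.pos1,
            true_pos2=sv.pos2,
            genes=genes,
            census_hit=bool(set(genes) & census),
        )
        return sv, ev

    for i in range(cfg.n_background_svs):
        sv, ev = random_sv("bg", i)
        tumor.append(sv)
        events.append(ev)
    for i in range(cfg.n_germline_svs):
        sv, ev = random_sv("gl", i)
        tumor.append(sv)
        ctl = sv
        if cfg.germline_jitter_bp:
            ctl = SvRecord(
                **{
                    **asdict(sv),
                    "pos1": sv.pos1 + int(rng.integers(-cfg.germline_jitter_bp, cfg.germline_jitter_bp + 1)),
                    "pos2": sv.pos2 + int(rng.integers(-cfg.germline_jitter_bp, cfg.germline_jitter_bp + 1)),
                }
            ).canonical()
        control.append(ctl)
        events.append(ev)
    return events, tumor, control


def simulate_junctions(
    genome: GenomeSequences,
    cfg: SimConfig,
    n: int,
    rng: np.random.Generator | None = None,
) -> tuple[list[dict], list[str]]:
    """Draw ``n`` coding-joint junctions with known chemistry at random positions.

    A lightweight companion to :func:`simulate_events` for large-n junction
    statistics: no planted sites or SV records, just (chew, P, N) draws per
    the configured distributions applied to uniformly chosen breakpoints.
    Returns (truth dicts, junction sequences); each truth dict records the
    breakpoints and drawn chemistry so the junction is re-derivable.
    """
    rng = rng or np.random.default_rng(cfg.seed + 3)
    a = cfg.anchor_bp
    names = list(genome.contigs)
    truths, seqs = [], []
    for _ in range(n):
        c1 = names[int(rng.integers(0, len(names)))]
        c2 = names[int(rng.integers(0, len(names)))]
        p1 = int(rng.integers(a + 10, genome.length(c1) - a - 10))
        p2 = int(rng.integers(a + 10, genome.length(c2) - a - 10))
        chew_l = _draw_chew(cfg, rng)
        chew_r = _draw_chew(cfg, rng)
        p_l = int(rng.integers(0, cfg.p_open_max + 1)) if chew_l == 0 else 0
        p_r = int(rng.integers(0, cfg.p_open_max + 1)) if chew_r == 0 else 0
        n_len = int(rng.poisson(cfg.n_len_poisson_lambda))
        n_seq = _rand_bases(n_len, rng)
        jx = _build_junction(genome, c1, p1, c2, p2, chew_l, chew_r, p_l, p_r, n_seq, a)
        truths.append(
            {
                "chrom1": c1,
                "pos1": p1,
                "chrom2": c2,
                "pos2": p2,
                "chew_left": chew_l,
                "chew_right": chew_r,
                "p_left": p_l,
                "p_right": p_r,
                "n_len": n_len,
                "n_seq": n_seq,
            }
        )
        seqs.append(jx)
    return truths, seqs


def simulate(cfg: SimConfig) -> SimResult:
    """Run genome generation, site planting and event simulation end to end."""
    rng = np.random.default_rng(cfg.seed)
    genome, models = generate_genome(cfg, rng)
    genome, sites = plant_sites(genome, cfg, rng)
    gene_names = sorted({m.gene for m in models})
    k = min(cfg.n_census_genes, len(gene_names))
    census = (
        {gene_names[int(i)] for i in rng.choice(len(gene_names), size=k, replace=False)}
        if k
        else set()
    )
    events, tumor, control = simulate_events(genome, sites, cfg, rng, models, census)
    return SimResult(
        cfg=cfg,
        genome=genome,
        models=models,
        sites=sites,
        events=events,
        tumor=tumor,
        control=control,
        census=census,
    )


def emit(outdir: str | os.PathLike, sim: SimResult) -> dict[str, str]:
    """Write ref.fa, genes.gff3, tumor/control BEDPE, junctions.fa, truth.tsv,
    census.tsv — all readable back through io_formats.  Deterministic given
    the SimResult."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "ref": os.path.join(outdir, "ref.fa"),
        "genes": os.path.join(outdir, "genes.gff3"),
        "tumor": os.path.join(outdir, "tumor.bedpe"),
        "control": os.path.join(outdir, "control.bedpe"),
        "junctions": os.path.join(outdir, "junctions.fa"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "census": os.path.join(outdir, "census.tsv"),
    }
    write_fasta(sim.genome, paths["ref"])
    write_gff3(sim.models, paths["genes"])
    write_bedpe(sim.tumor, paths["tumor"])
    write_bedpe(sim.control, paths["control"])
    with open(paths["junctions"], "w") as fh:
        for ev in sim.events:
            if ev.junction_seq:
                fh.write(f">{ev.event_id}\n{ev.junction_seq}\n")
    rows = []
    for ev in sim.events:
        rows.append(
            {
                "event_id": ev.event_id,
                "mechanism": ev.mechanism,
                "joint_type": ev.joint_type or "",
                "chrom1": ev.sv.chrom1,
                "pos1": ev.sv.pos1,
                "strand1": ev.sv.strand1,
                "chrom2": ev.sv.chrom2,
                "pos2": ev.sv.pos2,
                "strand2": ev.sv.strand2,
                "sv_type": ev.sv.sv_type,
                "true_pos1": ev.true_pos1,
                "true_pos2": ev.true_pos2,
                "site1": ev.site1 or "",
                "site2": ev.site2 or "",
                "chew_left": ev.chew_left,
                "chew_right": ev.chew_right,
                "p_left": ev.p_left,
                "p_right": ev.p_right,
                "n_len": ev.n_len,
                "n_seq": ev.n_seq,
                "junction_seq": ev.junction_seq or "",
                "genes": ",".join(ev.genes),
                "census_hit": int(ev.census_hit),
            }
        )
    pd.DataFrame(rows).to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["census"], "w") as fh:
        fh.write("Gene Symbol\n")
        for g in sorted(sim.census):
            fh.write(f"{g}\n")
    return paths
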