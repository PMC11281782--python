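"""Readers and writers for every external format the pipeline touches.

Internal coordinates are 0-based half-open everywhere.  BEDPE is read as-is
(already 0-based); VCF positions are shifted by -1 on read and +1 on write.
The breakpoint position of a BEDPE record is the *start* of each interval;
wider-than-one-base intervals are accepted with a logged precision warning.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import fmt_one_decimal

logger = logging.getLogger(__name__)

SV_TYPES = {"DEL", "INV", "DUP", "TRA", "BND"}
STRANDS = {"+", "-"}

__all__ = [
    "FormatError",
    "GenomeSequences",
    "SvRecord",
    "TranscriptModel",
    "read_fasta",
    "write_fasta",
    "read_bedpe",
    "write_bedpe",
    "read_vcf_svs",
    "write_vcf_svs",
    "read_gene_models",
    "write_gff3",
    "write_report_tables",
]


class FormatError(ValueError):
    """Malformed input file; message names the offending line where known."""


# ---------------------------------------------------------------------------
# reference genome


@dataclass
class GenomeSequences:
    """Uppercase DNA sequences keyed by contig name.

    ``fetch`` uses 0-based half-open coordinates and returns a substring of
    length ``end - start``.
    """

    contigs: dict[str, str]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.contigs[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise ValueError(
                f"fetch {chrom}:{start}-{end} outside contig of length {len(seq)}"
            )
        return seq[start:end]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.contigs

    def length(self, chrom: str) -> int:
        return len(self.contigs[chrom])


_VALID_BASES = set("ACGTN")


def read_fasta(path: str | os.PathLike) -> GenomeSequences:
    """Load a FASTA file, uppercasing bases and rejecting non-ACGTN characters."""
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for FASTA record '{record.id}'")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FormatError(
                f"non-ACGTN characters {sorted(bad)} in FASTA record '{record.id}'"
            )
        if record.id in contigs:
            raise FormatError(f"duplicate contig name '{record.id}'")
        contigs[record.id] = seq
    if not contigs:
        raise FormatError(f"no FASTA records found in {path}")
    return GenomeSequences(contigs)


def write_fasta(genome: GenomeSequences, path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.contigs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# structural variants


@dataclass
class SvRecord:
    """One candidate rearrangement: two break positions with retained-side strands.

    ``strand1``/``strand2`` encode which side of each break is retained in the
    derivative chromosome: ``+`` keeps the sequence left of the break, ``-``
    keeps the sequence right of it.  ``pos1``/``pos2`` are 0-based break
    coordinates; for intra-chromosomal records ``pos1 <= pos2`` (canonical
    ordering is enforced on read).
    """

    sample_id: str
    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    sv_type: str
    sv_id: str = ""
    junction_seq: str | None = None

    def canonical(self) -> "SvRecord":
        if (self.chrom1, self.pos1) > (self.chrom2, self.pos2):
            return replace(
                self,
                chrom1=self.chrom2,
                pos1=self.pos2,
                strand1=self.strand2,
                chrom2=self.chrom1,
                pos2=self.pos1,
                strand2=self.strand1,
            )
        return self


def _check_sv_fields(strand1: str, strand2: str, sv_type: str, where: str) -> None:
    for s in (strand1, strand2):
        if s not in STRANDS:
            raise FormatError(f"unknown strand symbol '{s}' at {where}")
    if sv_type not in SV_TYPES:
        raise FormatError(f"unknown SV type '{sv_type}' at {where}")


def read_bedpe(path: str | os.PathLike, sample_id: str = "") -> list[SvRecord]:
    """Read 10+-column BEDPE (0-based half-open) into canonical SvRecords.

    Breakpoint positions are taken as the start of each interval.  Column 11,
    when present, is the SV type; otherwise the type is inferred from the
    contig pair and strands (DEL for +/-, DUP for -/+, INV otherwise; TRA
    across contigs).
    """
    records: list[SvRecord] = []
    if not sample_id:
        sample_id = os.path.splitext(os.path.basename(str(path)))[0]
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise FormatError(
                    f"{path} line {lineno}: expected >=10 BEDPE columns, got {len(fields)}"
                )
            chrom1, start1, end1, chrom2, start2, end2, name = fields[:7]
            strand1, strand2 = fields[8], fields[9]
            try:
                s1, e1, s2, e2 = int(start1), int(end1), int(start2), int(end2)
            except ValueError as exc:
                raise FormatError(f"{path} line {lineno}: non-integer coordinate") from exc
            if e1 < s1 or e2 < s2:
                raise FormatError(f"{path} line {lineno}: interval end < start")
            if e1 - s1 > 1 or e2 - s2 > 1:
                logger.warning(
                    "%s line %d: breakpoint interval wider than 1 bp; using start",
                    path,
                    lineno,
                )
            sv_type = fields[10] if len(fields) > 10 and fields[10] in SV_TYPES else ""
            if not sv_type:
                if chrom1 != chrom2:
                    sv_type = "TRA"
                elif (strand1, strand2) == ("+", "-"):
                    sv_type = "DEL"
                elif (strand1, strand2) == ("-", "+"):
                    sv_type = "DUP"
                else:
                    sv_type = "INV"
            _check_sv_fields(strand1, strand2, sv_type, f"{path} line {lineno}")
            rec = SvRecord(
                sample_id=sample_id,
                chrom1=chrom1,
                pos1=s1,
                strand1=strand1,
                chrom2=chrom2,
                pos2=s2,
                strand2=strand2,
                sv_type=sv_type,
                sv_id=name,
            ).canonical()
            records.append(rec)
    return records


def write_bedpe(records: Iterable[SvRecord], path: str | os.PathLike) -> None:
    """Write SvRecords as 11-column BEDPE (single-base intervals, type in col 11)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                "\t".join(
                    [
                        rec.chrom1,
                        str(rec.pos1),
                        str(rec.pos1 + 1),
                        rec.chrom2,
                        str(rec.pos2),
                        str(rec.pos2 + 1),
                        rec.sv_id or ".",
                        ".",
                        rec.strand1,
                        rec.strand2,
                        rec.sv_type,
                    ]
                )
                + "\n"
            )


# BND bracket notation -> (strand at this break, strand at mate).
# t[p[ : piece right of the mate joined after local sequence (local left kept).
_BND_STRANDS = {
    ("after", "["): ("+", "-"),
    ("after", "]"): ("+", "+"),
    ("before", "]"): ("-", "+"),
    ("before", "["): ("-", "-"),
}


def _parse_bnd_alt(alt: str) -> tuple[str, int, str, str]:
    """Return (mate_chrom, mate_pos0, strand_here, strand_mate) from a BND ALT."""
    bracket = "[" if "[" in alt else "]"
    _, middle, _ = alt.split(bracket)
    side = "before" if alt[0] in "[]" else "after"
    chrom, pos = middle.rsplit(":", 1)
    strand_here, strand_mate = _BND_STRANDS[(side, bracket)]
    return chrom, int(pos) - 1, strand_here, strand_mate


def read_vcf_svs(path: str | os.PathLike, sample_id: str = "") -> list[SvRecord]:
    """Read SVs from a VCF 4.2 file (SVTYPE/END for symbolic alleles, MATEID for BND).

    1-based VCF POS/END are converted to 0-based internal break coordinates;
    paired BND mates are merged into a single record.  Unpaired BND mates are
    skipped with a warning.
    """
    import pysam

    if not sample_id:
        sample_id = os.path.splitext(os.path.basename(str(path)))[0]
    records: list[SvRecord] = []
    bnd_seen: dict[str, object] = {}
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            svtype = rec.info.get("SVTYPE")
            if svtype is None:
                continue
            if svtype == "BND":
                mate_id = rec.info.get("MATEID")
                if isinstance(mate_id, tuple):
                    mate_id = mate_id[0]
                if mate_id in bnd_seen:
                    mate = bnd_seen.pop(mate_id)
                    m_chrom, m_pos, s_here, s_mate = _parse_bnd_alt(mate.alts[0])
                    sv_type = "TRA" if mate.chrom != m_chrom else "BND"
                    records.append(
                        SvRecord(
                            sample_id=sample_id,
                            chrom1=mate.chrom,
                            pos1=mate.pos - 1,
                            strand1=s_here,
                            chrom2=m_chrom,
                            pos2=m_pos,
                            strand2=s_mate,
                            sv_type=sv_type,
                            sv_id=(mate.id or "").replace("_1", "").replace("_2", ""),
                        ).canonical()
                    )
                else:
                    bnd_seen[rec.id] = rec
                continue
            end = rec.info.get("END", rec.stop)
            strand1, strand2 = {
                "DEL": ("+", "-"),
                "DUP": ("-", "+"),
                "INV": ("+", "+"),
            }.get(svtype, ("+", "-"))
            records.append(
                SvRecord(
                    sample_id=sample_id,
                    chrom1=rec.chrom,
                    pos1=rec.pos - 1,
                    strand1=strand1,
                    chrom2=rec.chrom,
                    pos2=int(end) - 1,
                    strand2=strand2,
                    sv_type=svtype,
                    sv_id=rec.id or "",
                ).canonical()
            )
    for orphan_id, orphan in bnd_seen.items():
        logger.warning("unpaired BND mate '%s' skipped", orphan_id)
    return records


def write_vcf_svs(
    records: Iterable[SvRecord],
    genome_lengths: Mapping[str, int],
    path: str | os.PathLike,
) -> None:
    """Write SvRecords as a minimal VCF 4.2 (symbolic alleles; TRA as BND pairs)."""
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    for name, length in genome_lengths.items():
        buf.write(f"##contig=<ID={name},length={length}>\n")
    buf.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
    buf.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
    buf.write('##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate id">\n')
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    rows = []
    for i, rec in enumerate(records):
        rid = rec.sv_id or f"sv{i}"
        if rec.chrom1 == rec.chrom2 and rec.sv_type in {"DEL", "DUP", "INV"}:
            rows.append(
                (
                    rec.chrom1,
                    rec.pos1 + 1,
                    rid,
                    "N",
                    f"<{rec.sv_type}>",
                    f"SVTYPE={rec.sv_type};END={rec.pos2 + 1}",
                )
            )
        else:
            # Emit a BND mate pair; bracket form encodes retained sides.
            forms = {v: k for k, v in _BND_STRANDS.items()}
            side1, br1 = forms[(rec.strand1, rec.strand2)]
            side2, br2 = forms[(rec.strand2, rec.strand1)]
            mate1 = f"{rec.chrom2}:{rec.pos2 + 1}"
            mate2 = f"{rec.chrom1}:{rec.pos1 + 1}"
            alt1 = f"N{br1}{mate1}{br1}" if side1 == "after" else f"{br1}{mate1}{br1}N"
            alt2 = f"N{br2}{mate2}{br2}" if side2 == "after" else f"{br2}{mate2}{br2}N"
            rows.append(
                (
                    rec.chrom1,
                    rec.pos1 + 1,
                    f"{rid}_1",
                    "N",
                    alt1,
                    f"SVTYPE=BND;MATEID={rid}_2",
                )
            )
            rows.append(
                (
                    rec.chrom2,
                    rec.pos2 + 1,
                    f"{rid}_2",
                    "N",
                    alt2,
                    f"SVTYPE=BND;MATEID={rid}_1",
                )
            )
    for chrom, pos, rid, ref, alt, info in sorted(rows, key=lambda r: (r[0], r[1])):
        buf.write(f"{chrom}\t{pos}\t{rid}\t{ref}\t{alt}\t.\tPASS\t{info}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# gene models


@dataclass
class TranscriptModel:
    """One transcript: strand, exon/CDS intervals and derived UTRs/introns.

    All intervals are 0-based half-open (start, end) tuples sorted by start.
    """

    transcript_id: str
    gene: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)

    @property
    def introns(self) -> list[tuple[int, int]]:
        gaps = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                gaps.append((e1, s2))
        return gaps

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def utrs(self) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
        """(5'UTR, 3'UTR) intervals: exonic sequence outside the CDS span."""
        if not self.cds:
            return [], []
        cds_start = min(s for s, _ in self.cds)
        cds_end = max(e for _, e in self.cds)
        left, right = [], []
        for s, e in self.exons:
            if s < cds_start:
                left.append((s, min(e, cds_start)))
            if e > cds_end:
                right.append((max(s, cds_end), e))
        if self.strand == "+":
            return left, right
        return right, left


def _models_from_gff3(path: str) -> list[TranscriptModel]:
    import gffutils

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for tx in db.features_of_type(("mRNA", "transcript")):
        gene = tx.attributes.get("gene_name", tx.attributes.get("Parent", [tx.id]))[0]
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(tx, featuretype="exon")
        )
        cds = sorted((f.start - 1, f.end) for f in db.children(tx, featuretype="CDS"))
        start, end = tx.start - 1, tx.end
        for s, e in exons + cds:
            if s < start or e > end:
                raise FormatError(
                    f"{path}: exon/CDS [{s},{e}) outside transcript '{tx.id}' bounds"
                )
        models.append(
            TranscriptModel(
                transcript_id=tx.id,
                gene=gene,
                chrom=tx.seqid,
                strand=tx.strand,
                start=start,
                end=end,
                exons=exons or [(start, end)],
                cds=cds,
            )
        )
    return models


def _models_from_bed12(path: str) -> list[TranscriptModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path} line {lineno}: expected 12 BED columns")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + sz) for o, sz in zip(starts, sizes)]
            for s, e in exons:
                if s < start or e > end:
                    raise FormatError(
                        f"{path} line {lineno}: exon [{s},{e}) outside transcript bounds"
                    )
            cds = []
            if thick_end > thick_start:
                for s, e in exons:
                    cs, ce = max(s, thick_start), min(e, thick_end)
                    if ce > cs:
                        cds.append((cs, ce))
            models.append(
                TranscriptModel(
                    transcript_id=name,
                    gene=name,
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    exons=exons,
                    cds=cds,
                )
            )
    return models


def read_gene_models(path: str | os.PathLike) -> list[TranscriptModel]:
    """Read transcript models from GFF3 or BED12 (dispatch on extension)."""
    path = str(path)
    if path.endswith((".gff", ".gff3")):
        return _models_from_gff3(path)
    if path.endswith((".bed", ".bed12")):
        return _models_from_bed12(path)
    raise FormatError(f"unrecognized gene-model format for '{path}' (.gff3 or .bed12)")


def write_gff3(models: Sequence[TranscriptModel], path: str | os.PathLike) -> None:
    """Write transcript models as GFF3 (gene/mRNA/exon/CDS features, 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            attrs_gene = f"ID=gene:{m.gene};Name={m.gene}"
            fh.write(
                f"{m.chrom}\ttoy\tgene\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\t{attrs_gene}\n"
            )
            fh.write(
                f"{m.chrom}\ttoy\tmRNA\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={m.transcript_id};Parent=gene:{m.gene};gene_name={m.gene}\n"
            )
            for i, (s, e) in enumerate(m.exons):
                fh.write(
                    f"{m.chrom}\ttoy\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={m.transcript_id}.exon{i};Parent={m.transcript_id}\n"
                )
            for i, (s, e) in enumerate(m.cds):
                fh.write(
                    f"{m.chrom}\ttoy\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t0\t"
                    f"ID={m.transcript_id}.cds{i};Parent={m.transcript_id}\n"
                )


# ---------------------------------------------------------------------------
# report tables


def write_report_tables(
    tables: Mapping[str, pd.DataFrame], outdir: str | os.PathLike
) -> list[str]:
    """Write summary DataFrames as TSVs with deterministic column order.

    Columns whose name ends in ``percent`` or ``pct`` (or any float column)
    are rendered with one decimal, half away from zero, matching the report
    style used throughout the package.  Returns the written paths.
    """
    os.makedirs(outdir, exist_ok=True)
    written = []
    for name in sorted(tables):
        df = tables[name].copy()
        for col in df.columns:
            if pd.api.types.is_float_dtype(df[col]):
                df[col] = df[col].map(
                    lambda v: "" if pd.isna(v) else fmt_one_decimal(float(v))
                )
        path = os.path.join(str(outdir), f"{name}.tsv")
        df.to_csv(path, sep="\t", index=False)
        written.append(path)
    return written
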