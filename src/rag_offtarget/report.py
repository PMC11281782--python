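"""End-to-end pipeline orchestration and cohort summaries.

``run_pipeline`` executes the stages in order — control subtraction,
signature screen, breakpoint annotation, junction analysis, motif logo,
summary — for every sample in a cohort config, and writes the report TSVs
plus a run manifest (config hash, seed, version).  Rounding everywhere is
half away from zero to one decimal, the convention used for all printed
percentages and means (e.g. 24 SVs over 7 samples -> 3.4).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from ._util import round_half_away
from .annotation import (
    FeatureLabel,
    annotate_breakpoint,
    build_feature_index,
    feature_distribution,
    intersect_cancer_genes,
    read_census,
)
from .io_formats import (
    GenomeSequences,
    SvRecord,
    read_bedpe,
    read_fasta,
    read_gene_models,
    read_vcf_svs,
    write_report_tables,
)
from .junctions import (
    JointKind,
    classify_joint,
    cohort_junction_stats,
    junction_record_from_sv,
    partition_junction,
)
from .motif import build_motif_matrix, consensus_and_similarity, extract_signal_flank
from .signature import (
    RagCallDecision,
    SignatureConfig,
    SizeCategory,
    classify_rag_mediated,
    subtract_control_svs,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CohortSummary",
    "run_pipeline",
    "mean_svs_per_sample",
    "size_distribution_report",
]

SIZE_ORDER = [SizeCategory.LT_1KB, SizeCategory.KB_1_TO_10, SizeCategory.GT_10KB]


@dataclass
class CohortSummary:
    per_sample: pd.DataFrame
    per_genotype: pd.DataFrame
    feature_table: pd.DataFrame
    joints_table: pd.DataFrame
    sizes_table: pd.DataFrame
    pn_table: pd.DataFrame
    genes_table: pd.DataFrame
    logo_table: pd.DataFrame
    decisions: dict[str, list[RagCallDecision]] = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "report_samples": self.per_sample,
            "report_genotypes": self.per_genotype,
            "report_feature_distribution": self.feature_table,
            "report_joints": self.joints_table,
            "report_sizes": self.sizes_table,
            "report_pn": self.pn_table,
            "report_genes": self.genes_table,
            "report_logo": self.logo_table,
        }


def mean_svs_per_sample(counts: Sequence[int]) -> float:
    """Arithmetic mean of per-sample counts, half away from zero, one decimal."""
    if len(counts) == 0:
        raise ValueError("counts must be non-empty")
    return round_half_away(sum(counts) / len(counts), 1)


def size_distribution_report(
    decisions: Sequence[RagCallDecision],
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-group percentage in each recombinant-size category.

    Only intra-chromosomal events contribute to the percentages;
    inter-chromosomal events are counted separately in ``n_inter``.  Groups
    with zero intra-chromosomal events are omitted (logged).
    """
    if groups is None:
        groups = ["all"] * len(decisions)
    df = pd.DataFrame(
        {
            "group": list(groups),
            "category": [d.size_category for d in decisions],
        }
    )
    rows = []
    for group, sub in df.groupby("group", sort=True):
        intra = sub[sub.category != SizeCategory.NA]
        n_inter = int((sub.category == SizeCategory.NA).sum())
        if len(intra) == 0:
            logger.info("group %s has no intra-chromosomal events; row omitted", group)
            continue
        row = {"group": group, "n_intra": len(intra), "n_inter": n_inter}
        for cat in SIZE_ORDER:
            row[f"{cat.value}_pct"] = round_half_away(
                100.0 * (intra.category == cat).sum() / len(intra), 1
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _read_sv_file(path: str, sample_id: str) -> list[SvRecord]:
    if path.endswith((".vcf", ".vcf.gz")):
        return read_vcf_svs(path, sample_id)
    return read_bedpe(path, sample_id)


def _load_junction_seqs(path: str | None) -> dict[str, str]:
    if not path:
        return {}
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def run_pipeline(config: Mapping | str, outdir: str | None = None) -> CohortSummary:
    """Run subtract -> signature -> annotate -> junctions -> motif -> summarize.

    ``config`` is a mapping (or path to a YAML file) with keys: ``genome``,
    ``gene_models``, optional ``census``, ``samples`` (list of dicts with
    ``id``, ``genotype``, ``tumor``, optional ``control`` and ``junctions``),
    and an optional ``options`` block (window_bp, slop_bp, promoter_bp,
    downstream_bp, flank_bp, signal_offset_max, logo_width).  When ``outdir``
    is given the report TSVs and a manifest are written there.
    """
    if isinstance(config, str):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    opts = dict(config.get("options") or {})
    sig_cfg = SignatureConfig(
        window_bp=int(opts.get("window_bp", 21)),
        subtraction_slop_bp=int(opts.get("slop_bp", 50)),
    )
    flank_bp = int(opts.get("flank_bp", 50))
    signal_offset_max = int(opts.get("signal_offset_max", 0))
    logo_width = int(opts.get("logo_width", 7))
    promoter_bp = int(opts.get("promoter_bp", 2000))
    downstream_bp = int(opts.get("downstream_bp", 2000))

    genome = read_fasta(config["genome"])
    models = read_gene_models(config["gene_models"])
    index = build_feature_index(models, promoter_bp, downstream_bp)
    census = read_census(config["census"]) if config.get("census") else set()

    per_sample_rows = []
    labels_all: list[FeatureLabel] = []
    junction_stats_input = []
    junction_groups = []
    logo_seqs: list[str] = []
    per_sample_genes: dict[str, set[str]] = {}
    genotypes: dict[str, str] = {}
    decisions_by_sample: dict[str, list[RagCallDecision]] = {}
    size_decisions: list[RagCallDecision] = []
    size_groups: list[str] = []

    for sample in config.get("samples", []):
        sid = str(sample["id"])
        genotype = str(sample.get("genotype", ""))
        genotypes[sid] = genotype
        stage = "subtract"
        t0 = time.perf_counter()
        try:
            tumor = _read_sv_file(sample["tumor"], sid)
            control = (
                _read_sv_file(sample["control"], sid) if sample.get("control") else []
            )
            somatic = subtract_control_svs(tumor, control, sig_cfg.subtraction_slop_bp)
            stage = "signature"
            decisions = [classify_rag_mediated(sv, genome, sig_cfg) for sv in somatic]
            rag = [d for d in decisions if d.is_rag_mediated]
            decisions_by_sample[sid] = decisions
            stage = "annotate"
            labels = []
            genes: set[str] = set()
            for d in rag:
                for chrom, pos in ((d.sv.chrom1, d.sv.pos1), (d.sv.chrom2, d.sv.pos2)):
                    lab = annotate_breakpoint((chrom, pos), index)
                    labels.append(lab)
                    if lab.gene:
                        genes.add(lab.gene)
            labels_all.extend(labels)
            per_sample_genes[sid] = genes
            stage = "junctions"
            junction_seqs = _load_junction_seqs(sample.get("junctions"))
            for d in rag:
                sv = d.sv
                if sv.sv_id in junction_seqs:
                    sv.junction_seq = junction_seqs[sv.sv_id]
                rec = junction_record_from_sv(sv, genome, flank_bp)
                jt = classify_joint(sv, rec, genome, signal_offset_max)
                if rec.junction_seq:
                    part = partition_junction(rec)
                    junction_stats_input.append((part, jt))
                    junction_groups.append(genotype or sid)
                size_decisions.append(d)
                size_groups.append(genotype or sid)
            stage = "motif"
            for d in rag:
                for pos_pair, hits in (
                    ((d.sv.chrom1, d.sv.pos1), d.hits_bp1),
                    ((d.sv.chrom2, d.sv.pos2), d.hits_bp2),
                ):
                    if hits:  # best (smallest-offset) hit only
                        seq = extract_signal_flank(
                            genome, pos_pair[0], pos_pair[1], hits[0], logo_width
                        )
                        if seq:
                            logo_seqs.append(seq)
            per_sample_rows.append(
                {
                    "sample": sid,
                    "genotype": genotype,
                    "n_svs_total": len(tumor),
                    "n_svs_somatic": len(somatic),
                    "n_rag_positive": len(rag),
                }
            )
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{stage}' failed for sample '{sid}': {exc}") from exc
        logger.info("sample %s processed in %.2fs", sid, time.perf_counter() - t0)

    per_sample = pd.DataFrame(
        per_sample_rows,
        columns=["sample", "genotype", "n_svs_total", "n_svs_somatic", "n_rag_positive"],
    )
    if len(per_sample):
        per_genotype = (
            per_sample.groupby("genotype")[["n_svs_somatic", "n_rag_positive"]]
            .agg(["count", "mean"])
            .pipe(lambda df: df.set_axis(["_".join(c) for c in df.columns], axis=1))
            .reset_index()
            .rename(
                columns={
                    "n_svs_somatic_count": "n_samples",
                    "n_svs_somatic_mean": "mean_svs_per_sample",
                    "n_rag_positive_mean": "mean_rag_per_sample",
                }
            )
            .drop(columns=["n_rag_positive_count"])
        )
        for col in ("mean_svs_per_sample", "mean_rag_per_sample"):
            per_genotype[col] = per_genotype[col].map(lambda v: round_half_away(v, 1))
    else:
        per_genotype = pd.DataFrame(
            columns=["genotype", "n_samples", "mean_svs_per_sample", "mean_rag_per_sample"]
        )

    feature_table = feature_distribution(labels_all)
    pn_table = cohort_junction_stats(junction_stats_input, junction_groups)
    joints_table = (
        pn_table[["group", "n_junctions", "hybrid_pct"]].copy()
        if len(pn_table)
        else pd.DataFrame(columns=["group", "n_junctions", "hybrid_pct"])
    )
    sizes_table = size_distribution_report(size_decisions, size_groups)
    if census and per_sample_genes:
        genes_per_sample, genes_means = intersect_cancer_genes(
            per_sample_genes, census, genotypes
        )
        genes_table = genes_per_sample.merge(genes_means, on="genotype", how="left")
    else:
        genes_table = pd.DataFrame(
            columns=["sample", "genotype", "n_genes", "n_cancer_genes"]
        )
    if logo_seqs:
        matrix = build_motif_matrix(logo_seqs)
        consensus, match, mean_match = consensus_and_similarity(matrix)
        logo_table = pd.DataFrame(
            {
                "position": list(range(1, matrix.width + 1)),
                "A": matrix.counts[0],
                "C": matrix.counts[1],
                "G": matrix.counts[2],
                "T": matrix.counts[3],
                "ic_bits": [round(v, 4) for v in matrix.ic_bits],
                "consensus": list(consensus),
            }
        )
    else:
        logo_table = pd.DataFrame(
            columns=["position", "A", "C", "G", "T", "ic_bits", "consensus"]
        )

    summary = CohortSummary(
        per_sample=per_sample,
        per_genotype=per_genotype,
        feature_table=feature_table,
        joints_table=joints_table,
        sizes_table=sizes_table,
        pn_table=pn_table,
        genes_table=genes_table,
        logo_table=logo_table,
        decisions=decisions_by_sample,
    )
    if outdir:
        write_report_tables(summary.tables(), outdir)
        manifest = {
            "config_sha256": hashlib.sha256(
                json.dumps(config, sort_keys=True, default=str).encode()
            ).hexdigest(),
            "version": __version__,
            "seed": config.get("seed"),
            "options": {
                "window_bp": sig_cfg.window_bp,
                "slop_bp": sig_cfg.subtraction_slop_bp,
                "flank_bp": flank_bp,
                "signal_offset_max": signal_offset_max,
                "logo_width": logo_width,
                "promoter_bp": promoter_bp,
                "downstream_bp": downstream_bp,
            },
            "n_samples": len(per_sample),
        }
        with open(os.path.join(outdir, "run_manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return summary
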