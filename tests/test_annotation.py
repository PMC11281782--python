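import numpy as np
import pytest

import rag_offtarget as ro
from rag_offtarget.annotation import (
    CATEGORY_ORDER,
    FeatureCategory,
    FeatureLabel,
    annotate_breakpoint,
    build_feature_index,
    feature_distribution,
    intersect_cancer_genes,
)
from rag_offtarget.io_formats import TranscriptModel


def _tx(gene, chrom, strand, exons, cds=None, tid=None):
    return TranscriptModel(
        transcript_id=tid or f"{gene}.t1",
        gene=gene,
        chrom=chrom,
        strand=strand,
        start=exons[0][0],
        end=exons[-1][1],
        exons=exons,
        cds=cds or [],
    )


PRECEDENCE = {
    FeatureCategory.UTR5: 0,
    FeatureCategory.UTR3: 0,
    FeatureCategory.EXON: 1,
    FeatureCategory.INTRON: 2,
    FeatureCategory.PROMOTER: 3,
    FeatureCategory.DOWNSTREAM: 4,
}


def brute_force_label(models, promoter, downstream, chrom, pos):
    """All-intervals overlap scan applying the documented precedence."""
    candidates = []
    for m in models:
        if m.chrom != chrom:
            continue
        utr5, utr3 = m.utrs()
        feats = (
            [(FeatureCategory.EXON, iv) for iv in m.exons]
            + [(FeatureCategory.INTRON, iv) for iv in m.introns]
            + [(FeatureCategory.UTR5, iv) for iv in utr5]
            + [(FeatureCategory.UTR3, iv) for iv in utr3]
        )
        if m.strand == "+":
            feats.append((FeatureCategory.PROMOTER, (max(0, m.start - promoter), m.start)))
            feats.append((FeatureCategory.DOWNSTREAM, (m.end, m.end + downstream)))
        else:
            feats.append((FeatureCategory.PROMOTER, (m.end, m.end + promoter)))
            feats.append((FeatureCategory.DOWNSTREAM, (max(0, m.start - downstream), m.start)))
        for cat, (s, e) in feats:
            if s <= pos < e:
                candidates.append((PRECEDENCE[cat], abs(pos - m.tss), m.gene, cat))
    if not candidates:
        return FeatureCategory.INTERGENIC, None
    candidates.sort()
    return candidates[0][3], candidates[0][2]


class TestAnnotateBreakpoint:
    def test_promoter_clipped_at_contig_start(self):
        m = _tx("GA", "c", "+", [(1000, 2000)])
        idx = build_feature_index([m], promoter_bp=2000)
        assert annotate_breakpoint(("c", 500), idx).category is FeatureCategory.PROMOTER
        assert annotate_breakpoint(("c", 0), idx).category is FeatureCategory.PROMOTER

    def test_minus_strand_promoter_right_of_transcript(self):
        m = _tx("GB", "c", "-", [(1000, 2000)])
        idx = build_feature_index([m])
        assert annotate_breakpoint(("c", 2500), idx).category is FeatureCategory.PROMOTER
        assert annotate_breakpoint(("c", 500), idx).category is FeatureCategory.DOWNSTREAM

    def test_utr_takes_precedence_over_exon(self):
        m = _tx("GC", "c", "+", [(100, 400)], cds=[(200, 300)])
        idx = build_feature_index([m])
        assert annotate_breakpoint(("c", 150), idx).category is FeatureCategory.UTR5
        assert annotate_breakpoint(("c", 250), idx).category is FeatureCategory.EXON
        assert annotate_breakpoint(("c", 350), idx).category is FeatureCategory.UTR3

    def test_intron_beats_other_genes_promoter(self):
        a = _tx("GA", "c", "+", [(100, 200), (5000, 5200)])
        b = _tx("GB", "c", "+", [(4000, 4500)])  # promoter [2000,4000)
        idx = build_feature_index([a, b])
        lab = annotate_breakpoint(("c", 3000), idx)
        assert lab.category is FeatureCategory.INTRON and lab.gene == "GA"

    def test_intergenic_far_from_any_gene(self):
        m = _tx("GD", "c", "+", [(100, 200)])
        idx = build_feature_index([m])
        lab = annotate_breakpoint(("c", 50_000), idx)
        assert lab.category is FeatureCategory.INTERGENIC and lab.gene is None

    def test_matches_bruteforce_oracle_on_simulated_annotation(self, sim_small):
        models = sim_small.models
        idx = build_feature_index(models)
        rng = np.random.default_rng(42)
        chroms = list(sim_small.genome.contigs)
        for _ in range(200):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            pos = int(rng.integers(0, sim_small.genome.length(chrom)))
            lab = annotate_breakpoint((chrom, pos), idx)
            want_cat, want_gene = brute_force_label(models, 2000, 2000, chrom, pos)
            assert lab.category is want_cat, (chrom, pos)
            assert lab.gene == want_gene


class TestFeatureDistribution:
    def test_reported_category_counts_give_reported_percentages(self):
        counts = {
            FeatureCategory.EXON: 9,
            FeatureCategory.INTRON: 20,
            FeatureCategory.UTR3: 6,
            FeatureCategory.UTR5: 2,
            FeatureCategory.PROMOTER: 6,
            FeatureCategory.DOWNSTREAM: 9,
        }
        labels = [FeatureLabel(cat, "G") for cat, n in counts.items() for _ in range(n)]
        df = feature_distribution(labels).set_index("category")
        expected = {
            "EXON": 17.3,
            "INTRON": 38.5,
            "UTR3": 11.5,
            "UTR5": 3.8,
            "PROMOTER": 11.5,
            "DOWNSTREAM": 17.3,
        }
        for cat, pct in expected.items():
            assert df.loc[cat, "percent"] == pct

    def test_single_label_is_100_percent(self):
        df = feature_distribution([FeatureLabel(FeatureCategory.EXON, "G")])
        assert df.percent.tolist() == [100.0]

    def test_counts_partition_and_percentages_match_arithmetic(self):
        rng = np.random.default_rng(5)
        cats = [CATEGORY_ORDER[i] for i in rng.integers(0, len(CATEGORY_ORDER), size=97)]
        labels = [
            FeatureLabel(c, None if c is FeatureCategory.INTERGENIC else "G") for c in cats
        ]
        df = feature_distribution(labels)
        assert df["count"].sum() == len(labels)
        for _, row in df.iterrows():
            want = round(100.0 * row["count"] / len(labels) * 10 + 0.5) / 10  # half away
            assert abs(row["percent"] - 100.0 * row["count"] / len(labels)) <= 0.05
        assert abs(df.percent.sum() - 100.0) <= 0.3

    def test_empty_input_yields_empty_table(self):
        assert feature_distribution([]).empty


class TestCancerGeneIntersection:
    def test_simple_intersection(self):
        per_sample, _ = intersect_cancer_genes({"s1": {"A", "B"}}, {"B", "C"})
        row = per_sample.iloc[0]
        assert (row.n_genes, row.n_cancer_genes) == (2, 1)

    def test_empty_gene_set(self):
        per_sample, _ = intersect_cancer_genes({"s1": set()}, {"B"})
        row = per_sample.iloc[0]
        assert (row.n_genes, row.n_cancer_genes) == (0, 0)

    def test_empty_census_rejected(self):
        with pytest.raises(ValueError):
            intersect_cancer_genes({"s1": {"A"}}, set())

    def test_genotype_means_match_truth_on_simulated_cohort(self):
        sims = [ro.simulate(ro.SimConfig(seed=s, sample_id=f"s{s}")) for s in (31, 32)]
        per_sample_genes = {}
        genotypes = {}
        census = sims[0].census
        for sim in sims:
            rag_genes = set()
            for e in sim.events:
                if e.mechanism == "RAG":
                    rag_genes.update(e.genes)
            per_sample_genes[sim.cfg.sample_id] = rag_genes
            genotypes[sim.cfg.sample_id] = "Rag1_cc"
        per_sample, means = intersect_cancer_genes(per_sample_genes, census, genotypes)
        manual = np.mean(
            [len(per_sample_genes[s] & census) for s in per_sample_genes]
        )
        assert means.loc[0, "mean_cancer_genes"] == pytest.approx(round(manual, 1), abs=0.05)
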