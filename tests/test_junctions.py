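import numpy as np
import pytest
from hypothesis import given, strategies as st

import rag_offtarget as ro
from rag_offtarget._util import revcomp
from rag_offtarget.junctions import (
    JointKind,
    JunctionRecord,
    classify_joint,
    cohort_junction_stats,
    junction_record_from_sv,
    partition_junction,
    recover_chemistry_means,
)
from rag_offtarget.simulate import SimConfig, generate_genome, simulate_junctions

dna = st.text(alphabet="ACGT", min_size=20, max_size=60)


def oracle_partition(jx: str, left: str, right: str, cap: int = 10):
    """Independent enumeration applying the documented conventions.

    Finds the maximal flank matches by explicit enumeration over all prefix
    and suffix lengths, assigns overlap to the left match, then enumerates
    every (p_left, p_right) split maximizing p_left first, then p_right.
    """
    raw_l = max(
        (k for k in range(len(jx) + 1) if k <= len(left) and jx[:k] == left[:k]),
        default=0,
    )
    raw_r = max(
        (
            k
            for k in range(len(jx) + 1)
            if k <= len(right) and (k == 0 or jx[-k:] == right[-k:])
        ),
        default=0,
    )
    if raw_l + raw_r <= len(jx):
        lm, rm = raw_l, raw_r
    else:
        lm, rm = raw_l, len(jx) - raw_l
    insert = jx[lm : len(jx) - rm]
    rl = left[:raw_l]
    rr = right[len(right) - raw_r :]
    best = None
    for pl in range(min(cap, len(insert), len(rl)), -1, -1):
        if pl and insert[:pl] != revcomp(rl[-pl:]):
            continue
        for pr in range(min(cap, len(insert) - pl, len(rr)), -1, -1):
            if pr and insert[len(insert) - pr :] != revcomp(rr[:pr]):
                continue
            best = (pl, pr, len(insert) - pl - pr)
            break
        break
    return {
        "left_match": lm,
        "right_match": rm,
        "del_left": len(left) - raw_l,
        "del_right": len(right) - raw_r,
        "p": best,
    }


class TestPartition:
    def test_perfect_join_has_no_insert_or_chew(self):
        left, right = "ACGTACGTACGTACGTACGTG", "TTGCATGCATGCATGCATGCA"
        rec = JunctionRecord("j", left + right, left, right)
        p = partition_junction(rec)
        assert p.insert_seq == "" and p.n_len == 0
        assert p.del_left == 0 and p.del_right == 0
        assert p.p_left_len == 0 and p.p_right_len == 0

    def test_canonical_p_addition(self):
        # left flank ends ...GATC; insert "GA" is the revcomp of terminal "TC"
        left = "A" * 16 + "GATC"
        right = "TTTTGGGGCCCCAAAATTTT"
        rec = JunctionRecord("j", left + "GA" + right, left, right)
        p = partition_junction(rec)
        assert (p.p_left_len, p.n_len, p.p_right_len) == (2, 0, 0)

    def test_pure_n_insert(self):
        left = "C" * 20
        right = "G" * 20
        rec = JunctionRecord("j", left + "AAA" + right, left, right)
        p = partition_junction(rec)
        # A is not complementary to C or G: the whole insert is non-templated
        assert (p.p_left_len, p.p_right_len, p.n_len) == (0, 0, 3)

    def test_empty_junction_rejected(self):
        with pytest.raises(ValueError):
            partition_junction(JunctionRecord("j", "", "A" * 20, "C" * 20))

    @given(left=dna, right=dna, insert=st.text(alphabet="ACGT", max_size=15))
    def test_length_conservation_invariants(self, left, right, insert):
        jx = left + insert + right
        p = partition_junction(JunctionRecord("j", jx, left, right))
        assert p.left_match_len + len(p.insert_seq) + p.right_match_len == len(jx)
        assert p.p_left_len + p.n_len + p.p_right_len == len(p.insert_seq)
        if p.p_left_len:
            retained = left[: len(left) - p.del_left]
            assert p.insert_seq[: p.p_left_len] == revcomp(retained[-p.p_left_len :])

    def test_matches_enumeration_oracle_on_simulated_junctions(self):
        cfg = SimConfig(seed=21)
        rng = np.random.default_rng(21)
        genome, _ = generate_genome(cfg, rng)
        truths, seqs = simulate_junctions(genome, cfg, 500, rng)
        a = cfg.anchor_bp
        for t, jx in zip(truths, seqs):
            left = genome.fetch(t["chrom1"], t["pos1"] - a, t["pos1"])
            right = genome.fetch(t["chrom2"], t["pos2"], t["pos2"] + a)
            p = partition_junction(JunctionRecord("j", jx, left, right))
            want = oracle_partition(jx, left, right)
            assert (p.del_left, p.del_right) == (want["del_left"], want["del_right"])
            assert (p.p_left_len, p.p_right_len, p.n_len) == want["p"]

    def test_truth_recovered_when_unambiguous(self):
        cfg = SimConfig(seed=22)
        rng = np.random.default_rng(22)
        genome, _ = generate_genome(cfg, rng)
        truths, seqs = simulate_junctions(genome, cfg, 500, rng)
        a = cfg.anchor_bp
        n_checked = 0
        for t, jx in zip(truths, seqs):
            left = genome.fetch(t["chrom1"], t["pos1"] - a, t["pos1"])
            right = genome.fetch(t["chrom2"], t["pos2"], t["pos2"] + a)
            p = partition_junction(JunctionRecord("j", jx, left, right))
            # unambiguous: apparent boundaries equal the generative ones
            if (p.del_left, p.del_right) == (t["chew_left"], t["chew_right"]) and (
                p.p_left_len,
                p.p_right_len,
            ) == (t["p_left"], t["p_right"]):
                assert p.n_len == t["n_len"]
                n_checked += 1
        # chance base matches make a minority of junctions ambiguous; the
        # exact-recovery fraction is bounded below to catch gross regressions
        assert n_checked > 150

    def test_reverse_complement_swaps_sides(self):
        """RC of a junction swaps P and chew sides and preserves N length."""
        cfg = SimConfig(seed=23)
        rng = np.random.default_rng(23)
        genome, _ = generate_genome(cfg, rng)
        truths, seqs = simulate_junctions(genome, cfg, 300, rng)
        a = cfg.anchor_bp
        n_checked = 0
        for t, jx in zip(truths, seqs):
            left = genome.fetch(t["chrom1"], t["pos1"] - a, t["pos1"])
            right = genome.fetch(t["chrom2"], t["pos2"], t["pos2"] + a)
            rec = JunctionRecord("j", jx, left, right)
            p = partition_junction(rec)
            q = partition_junction(rec.reverse_complemented())
            assert (q.del_left, q.del_right) == (p.del_right, p.del_left)
            # P-side symmetry holds when the two maximal palindromic segments,
            # measured independently on the full insert, do not compete for
            # the same bases (greedy left-first tie-break otherwise applies)
            ins = p.insert_seq
            ret_l = left[: len(left) - p.del_left]
            ret_r = right[p.del_right :]
            pl_max = max(
                (k for k in range(len(ins) + 1) if ins[:k] == revcomp(ret_l[len(ret_l) - k :])),
                default=0,
            )
            pr_max = max(
                (k for k in range(len(ins) + 1) if k == 0 or ins[-k:] == revcomp(ret_r[:k])),
                default=0,
            )
            if pl_max + pr_max <= len(ins):
                assert (q.p_left_len, q.p_right_len) == (p.p_right_len, p.p_left_len)
                assert q.n_len == p.n_len
                n_checked += 1
        assert n_checked > 200


class TestClassifyJoint:
    def _del_sv(self, pos1, pos2, chrom="c"):
        return ro.SvRecord("s", chrom, pos1, "+", chrom, pos2, "-", "DEL", "sv1")

    def test_signal_joint_both_heptamers_abut(self):
        # end1 retains left with revcomp heptamer ending at the break;
        # end2 retains right with heptamer starting at the break
        seq = "T" * 43 + revcomp("CACAGTG") + "T" * 100 + "CACAGTG" + "T" * 50
        g = ro.GenomeSequences({"c": seq})
        jt = classify_joint(self._del_sv(50, 150), None, g)
        assert jt.value is JointKind.SIGNAL
        assert jt.signal_end_1 and jt.signal_end_2
        assert jt.low_confidence  # no junction sequence provided

    def test_coding_joint_no_motifs(self):
        g = ro.GenomeSequences({"c": "T" * 300})
        jt = classify_joint(self._del_sv(50, 250), None, g)
        assert jt.value is JointKind.CODING

    def test_hybrid_exactly_one_signal_end(self):
        seq = "T" * 43 + revcomp("CACAGTG") + "T" * 250
        g = ro.GenomeSequences({"c": seq})
        jt = classify_joint(self._del_sv(50, 250), None, g)
        assert jt.value is JointKind.HYBRID
        assert jt.signal_end_1 != jt.signal_end_2

    def test_simulated_cohort_recovers_truth(self, sim_cohort50):
        sim = sim_cohort50
        rag = [e for e in sim.events if e.mechanism == "RAG"]
        assert rag
        for e in rag:
            rec = junction_record_from_sv(e.sv, sim.genome, sim.cfg.anchor_bp)
            jt = classify_joint(e.sv, rec, sim.genome)
            assert jt.value.value == e.joint_type, e.event_id


class TestCohortStats:
    def _part(self, pl=0, pr=0, n=0):
        from rag_offtarget.junctions import PNPartition

        return PNPartition(10, 10, "X" * (pl + pr + n), pl, pr, n, 0, 0, 0)

    def _jt(self, kind):
        from rag_offtarget.junctions import JointType

        return JointType(kind, kind is JointKind.SIGNAL, False)

    def test_p_and_n_frequencies_50_50(self):
        recs = [
            (self._part(pl=2), self._jt(JointKind.CODING)),
            (self._part(n=3), self._jt(JointKind.CODING)),
        ]
        df = cohort_junction_stats(recs)
        assert df.loc[0, "p_frequency_pct"] == 50.0
        assert df.loc[0, "n_frequency_pct"] == 50.0

    def test_all_hybrid_gives_100_percent(self):
        recs = [(self._part(), self._jt(JointKind.HYBRID)) for _ in range(7)]
        df = cohort_junction_stats(recs)
        assert df.loc[0, "hybrid_pct"] == 100.0

    def test_statistics_match_independent_tabulation(self, sim_cohort50):
        sim = sim_cohort50
        recs, truth_hybrid, truth_p, truth_n = [], 0, 0, 0
        for e in sim.events:
            if e.mechanism != "RAG":
                continue
            rec = junction_record_from_sv(e.sv, sim.genome, sim.cfg.anchor_bp)
            part = partition_junction(rec)
            jt = classify_joint(e.sv, rec, sim.genome)
            recs.append((part, jt))
            truth_hybrid += e.joint_type == "HYBRID"
            truth_p += part.p_left_len + part.p_right_len > 0
            truth_n += part.n_len > 0
        df = cohort_junction_stats(recs)
        n = len(recs)
        assert df.loc[0, "hybrid_pct"] == pytest.approx(100 * truth_hybrid / n, abs=0.06)
        assert df.loc[0, "p_frequency_pct"] == pytest.approx(100 * truth_p / n, abs=0.06)
        assert df.loc[0, "n_frequency_pct"] == pytest.approx(100 * truth_n / n, abs=0.06)

    def test_empty_group_omitted(self):
        df = cohort_junction_stats([], [])
        assert df.empty


class TestChemistryRecovery:
    def test_corrected_means_match_generating_distributions(self):
        """Moment-corrected chew/P/N means land within 3 SE of the draws."""
        cfg = SimConfig(seed=29)
        rng = np.random.default_rng(29)
        genome, _ = generate_genome(cfg, rng)
        truths, seqs = simulate_junctions(genome, cfg, 1000, rng)
        a = cfg.anchor_bp
        parts, recs = [], []
        for t, jx in zip(truths, seqs):
            rec = JunctionRecord(
                "j",
                jx,
                genome.fetch(t["chrom1"], t["pos1"] - a, t["pos1"]),
                genome.fetch(t["chrom2"], t["pos2"], t["pos2"] + a),
            )
            recs.append(rec)
            parts.append(partition_junction(rec))
        est = recover_chemistry_means(parts, recs)
        n_ends = 2 * len(parts)
        p = cfg.chew_geom_p
        chew_mean = (1 - p) / p  # cap correction is < 0.05 for the defaults
        chew_se = np.sqrt((1 - p) / p**2 / n_ends)
        assert abs(est["mean_chew"] - chew_mean) < 3 * chew_se + 0.05
        n_uncut = n_ends * p
        p_mean = cfg.p_open_max / 2
        p_se = np.sqrt(((cfg.p_open_max + 1) ** 2 - 1) / 12 / n_uncut)
        assert abs(est["mean_p"] - p_mean) < 3 * p_se
        lam = cfg.n_len_poisson_lambda
        assert abs(est["mean_n"] - lam) < 3 * np.sqrt(lam / len(parts))
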