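import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from _oracles import sw_affine_score_oracle
from conftest import random_protein
from toxprospect.cluster import ClusterConfig
from toxprospect.screen import (
    ProspectionAccounting,
    ReferenceSet,
    ScreenConfig,
    ScreenHit,
    alignment_background,
    build_family_model,
    combine_strategies,
    compete,
    evalue,
    homology_screen,
    local_align,
    profile_screen,
)
from toxprospect.seqio import SequenceRecord
from toxprospect.synthetic import shuffled_decoys


class TestLocalAlign:
    def test_perfect_match_score(self):
        b62 = substitution_matrices.load("BLOSUM62")
        seq = "MKCLVPQW"
        score, span = local_align(seq, seq)
        assert score == sum(b62[a, a] for a in seq)
        assert span == ((0, 8), (0, 8))

    def test_mismatch_floor_is_empty_alignment(self):
        score, span = local_align("A", "W")
        assert score == 0.0 and span is None

    def test_matches_independent_affine_dp_oracle(self):
        b62 = substitution_matrices.load("BLOSUM62")
        config = ScreenConfig()
        rng = np.random.default_rng(0)
        for _ in range(200):
            a = random_protein(rng, int(rng.integers(5, 25)))
            b = random_protein(rng, int(rng.integers(5, 25)))
            want = sw_affine_score_oracle(
                a, b, lambda x, y: float(b62[x, y]), config.gap_open, config.gap_extend
            )
            assert local_align(a, b, config)[0] == pytest.approx(max(want, 0.0))


class TestEvalue:
    def test_zero_score_limit(self):
        config = ScreenConfig()
        assert evalue(0.0, config, 100, 200) == config.k * 100 * 200

    def test_direct_formula_value(self):
        config = ScreenConfig(lambda_=0.267, k=0.041)
        assert evalue(30.0, config, 100, 100) == pytest.approx(0.1362, abs=2e-4)

    def test_monotone_decreasing_in_score(self):
        config = ScreenConfig()
        es = [evalue(s, config, 150, 150) for s in (0, 10, 20, 40, 80)]
        assert es == sorted(es, reverse=True)


class TestHomologyScreen:
    def test_self_hit_with_keyword(self):
        orf = SequenceRecord("q1", "MKCLVPQWERTYHNASDFGH")
        ref = ReferenceSet(
            [SequenceRecord("t1", orf.seq)], {"t1": frozenset({"lectin"})}
        )
        hits, counts = homology_screen([orf], ref)
        assert len(hits) == 1 and hits[0].evalue < 1e-5
        assert counts == {"lectin": 1}

    def test_query_counted_under_every_keyword(self):
        seq = "MKCLVPQWERTYHNASDFGH"
        ref = ReferenceSet(
            [SequenceRecord("t1", seq), SequenceRecord("t2", seq)],
            {"t1": frozenset({"neurotoxin"}), "t2": frozenset({"protease"})},
        )
        hits, counts = homology_screen([SequenceRecord("q1", seq)], ref)
        assert counts == {"neurotoxin": 1, "protease": 1}
        assert sum(counts.values()) == 2  # one query, two keywords

    def test_unknown_keyword_rejected(self):
        with pytest.raises(ValueError, match="unknown keyword"):
            ReferenceSet(
                [SequenceRecord("t1", "MKLV")], {"t1": frozenset({"sparkly"})}
            )

    def test_shuffled_decoys_yield_no_hits(self, small_study):
        decoys = shuffled_decoys(small_study["records"][:40], seed=5)
        hits, counts = homology_screen(decoys, small_study["reference"])
        assert len({h.query_id for h in hits}) <= 1
        assert sum(counts.values()) <= 1

    def test_planted_homologs_all_recovered(self, small_study):
        hits, _ = homology_screen(small_study["records"], small_study["reference"])
        assert {h.query_id for h in hits} == {r.id for r in small_study["records"]}


class TestFamilyModel:
    def test_identical_seed_maximizes_consensus(self):
        aln = [SequenceRecord(f"s{i}", "MKCLV") for i in range(4)]
        model = build_family_model(aln, "fam")
        for col, aa in enumerate("MKCLV"):
            assert model.log_odds[col].argmax() == "ACDEFGHIKLMNPQRSTVWY".index(aa)

    def test_single_column_hand_computed_log_odds(self):
        # column {A, A, C}, uniform background, +1 additive pseudocounts:
        # p(A)=3/23, p(C)=2/23, p(other)=1/23 against 1/20
        aln = [SequenceRecord("a", "A"), SequenceRecord("b", "A"), SequenceRecord("c", "C")]
        uniform = {aa: 0.05 for aa in "ACDEFGHIKLMNPQRSTVWY"}
        model = build_family_model(aln, "toy", background=uniform, pseudocount=1.0)
        idx = "ACDEFGHIKLMNPQRSTVWY".index
        assert model.log_odds[0][idx("A")] == pytest.approx(math.log((3 / 23) / 0.05))
        assert model.log_odds[0][idx("C")] == pytest.approx(math.log((2 / 23) / 0.05))
        assert model.log_odds[0][idx("W")] == pytest.approx(math.log((1 / 23) / 0.05))

    def test_sequence_order_does_not_matter(self, small_study):
        aln = small_study["alignments"]["FAM0"]
        m1 = build_family_model(aln, "f")
        m2 = build_family_model(list(reversed(aln)), "f")
        assert np.allclose(m1.log_odds, m2.log_odds)

    def test_gap_majority_columns_dropped(self):
        aln = [
            SequenceRecord("a", "M-KL"),
            SequenceRecord("b", "M-KL"),
            SequenceRecord("c", "MAKL"),
        ]
        model = build_family_model(aln, "f")
        assert model.match_columns == [0, 2, 3]

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            build_family_model(
                [SequenceRecord("a", "MK"), SequenceRecord("b", "MKL")], "f"
            )


class TestCompete:
    def test_member_assigned_to_own_family(self, small_study):
        aln = small_study["alignments"]
        bg = alignment_background(list(aln.values()))
        models = [build_family_model(v, k, background=bg) for k, v in aln.items()]
        ok = sum(
            compete(t.mature_seq, models)[0] == t.family
            for t in small_study["truths"]
        )
        assert ok / len(small_study["truths"]) >= 0.95

    def test_single_model_consensus_wins(self):
        aln = [SequenceRecord(f"s{i}", "MKCLVWYHND") for i in range(3)]
        model = build_family_model(aln, "only")
        assert compete("MKCLVWYHND", [model])[0] == "only"

    def test_decoys_rejected_by_null(self, small_study):
        aln = small_study["alignments"]
        bg = alignment_background(list(aln.values()))
        models = [build_family_model(v, k, background=bg) for k, v in aln.items()]
        decoys = shuffled_decoys(
            [SequenceRecord(t.id, t.mature_seq) for t in small_study["truths"]], seed=7
        )
        accepted = sum(compete(d.seq, models)[0] is not None for d in decoys)
        assert accepted / len(decoys) <= 0.05

    def test_union_recall_dominates_single_strategies(self, small_study):
        # complementarity: the combined hit set recalls at least as much
        # as either route alone
        records, truths = small_study["records"], small_study["truths"]
        hom_hits, _ = homology_screen(records, small_study["reference"])
        aln = small_study["alignments"]
        bg = alignment_background(list(aln.values()))
        models = [build_family_model(v, k, background=bg) for k, v in aln.items()]
        prof_hits, _ = profile_screen(records, models)
        hom_ids = {h.query_id for h in hom_hits}
        prof_ids = {h.query_id for h in prof_hits}
        union = hom_ids | prof_ids
        planted = {t.id for t in truths}
        recall = lambda s: len(s & planted) / len(planted)
        assert recall(union) >= max(recall(hom_ids), recall(prof_ids))


class TestCombineStrategies:
    def test_published_inclusion_exclusion(self):
        acc = ProspectionAccounting(
            homology_total=262, homology_redundant=97, profile_total=318,
            overlap=115, previously_reported_homology=17, previously_reported_profile=23,
        )
        assert acc.homology_nonredundant == 165
        assert acc.final_count == 328

    def test_no_hits_give_zero(self):
        acc = combine_strategies([], [])
        assert acc.final_count == 0

    def test_disjoint_strategies_sum(self):
        hom = [ScreenHit(f"h{i}", "t", 50.0, "homology") for i in range(5)]
        prof = [ScreenHit(f"p{i}", "f", 10.0, "profile", family="f") for i in range(7)]
        acc = combine_strategies(hom, prof)
        assert acc.overlap == 0 and acc.final_count == 12

    def test_random_id_sets_match_set_algebra(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            universe = [f"id{i}" for i in range(30)]
            hom = sorted(set(rng.choice(universe, size=int(rng.integers(0, 20)))))
            prof = sorted(set(rng.choice(universe, size=int(rng.integers(0, 20)))))
            hom_only = [i for i in hom if i not in prof]
            prof_only = [i for i in prof if i not in hom]
            prev_h = [i for i in hom_only if rng.random() < 0.2]
            prev_p = [i for i in prof_only if rng.random() < 0.2]
            acc = combine_strategies(
                [ScreenHit(i, "t", 1.0, "homology") for i in hom],
                [ScreenHit(i, "f", 1.0, "profile", family="f") for i in prof],
                previously_reported_homology=prev_h,
                previously_reported_profile=prev_p,
            )
            want = len(set(hom) | set(prof)) - len(prev_h) - len(prev_p)
            assert acc.final_count == want
            assert acc.final_ids == sorted((set(hom) | set(prof)) - set(prev_h) - set(prev_p))

    def test_absent_previously_reported_id_warns_not_errors(self):
        acc = combine_strategies(
            [ScreenHit("a", "t", 1.0, "homology")], [],
            previously_reported_homology=["ghost"],
        )
        assert acc.warnings and "ghost" in acc.warnings[0]

    def test_redundant_homology_queries_deduplicated(self):
        seqs = {"a": "MKCLVPQWERTYHNASDFGH", "b": "MKCLVPQWERTYHNASDFGH",
                "c": "WWWWYYYYHHHHNNNNDDDD"}
        hits = [ScreenHit(i, "t", 9.0, "homology") for i in seqs]
        acc = combine_strategies(hits, [], orf_seqs=seqs,
                                 cluster_config=ClusterConfig())
        assert acc.homology_total == 3 and acc.homology_redundant == 1
        assert acc.final_count == 2
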