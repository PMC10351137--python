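import numpy as np
import pytest

from snp2enhancer.annotation import EQTLAnnotation, OverlapSummary
from snp2enhancer.io_formats import Variant
from snp2enhancer.motif import AllelicBindingScore
from snp2enhancer.prioritize import (
    CandidateRecord,
    assign_tiers,
    rank_candidates,
    records_to_dataframe,
)


def make_record(rsid="rs1", pos=100, r2=0.9, eqtl=True, n_tf=1, n_reg=1,
                flagged_delta=None, pvalue=1e-8):
    v = Variant("chrX", pos, rsid, "T", "C")
    ann = EQTLAnnotation(v, "AGTR2", "uterus", -0.5, pvalue) if eqtl else None
    overlaps = OverlapSummary(
        v, [(f"tf{i}", "CEBPB") for i in range(n_tf)],
        [f"reg{i}" for i in range(n_reg)])
    scores = []
    if flagged_delta is not None:
        scores.append(AllelicBindingScore(v, "CEBPB", 10.0, 10.0 + flagged_delta,
                                          0.0, 0.0, flagged_delta, 0, "+", 0, "+",
                                          flagged=True))
    return CandidateRecord(v, r2, eqtl=ann, overlaps=overlaps, motif_scores=scores)


class TestAssignTiers:
    def test_eqtl_without_peaks_stops_at_tier_two(self):
        (rec,) = assign_tiers([make_record(n_tf=0, n_reg=0)])
        assert rec.tier == 2

    def test_full_evidence_reaches_tier_four(self):
        (rec,) = assign_tiers([make_record(flagged_delta=-3.0)])
        assert rec.tier == 4

    def test_peaks_without_eqtl_stop_at_tier_one(self):
        (rec,) = assign_tiers([make_record(eqtl=False, flagged_delta=-3.0)])
        assert rec.tier == 1

    def test_requires_both_regulatory_and_tf_peaks(self):
        (only_tf,) = assign_tiers([make_record(n_reg=0)])
        (only_reg,) = assign_tiers([make_record(n_tf=0)])
        assert only_tf.tier == 2 and only_reg.tier == 2

    def test_pvalue_filter_gates_the_eqtl_tier(self):
        (rec,) = assign_tiers([make_record(pvalue=0.2)], pvalue_max=0.05)
        assert rec.tier == 1

    def test_removing_any_evidence_layer_never_raises_the_tier(self):
        full = make_record(flagged_delta=-3.0)
        assign_tiers([full])
        ablations = [
            make_record(eqtl=False, flagged_delta=-3.0),
            make_record(n_tf=0, flagged_delta=-3.0),
            make_record(n_reg=0, flagged_delta=-3.0),
            make_record(flagged_delta=None),
        ]
        assign_tiers(ablations)
        assert all(a.tier < full.tier for a in ablations)


class TestRankCandidates:
    def test_single_candidate_gets_rank_one(self):
        recs = assign_tiers([make_record()])
        assert rank_candidates(recs)[0].rank == 1

    def test_tier_dominates_every_other_key(self):
        low = make_record("rs_low", pos=1, r2=1.0, n_tf=9, flagged_delta=None)
        high = make_record("rs_high", pos=2, r2=0.81, n_tf=1, flagged_delta=-2.5)
        ranked = rank_candidates(assign_tiers([low, high]))
        assert [r.variant.rsid for r in ranked] == ["rs_high", "rs_low"]

    def test_tf_count_breaks_ties_after_delta(self):
        a = make_record("rs_a", pos=10, n_tf=1, flagged_delta=-3.0)
        b = make_record("rs_b", pos=20, n_tf=4, flagged_delta=-3.0)
        ranked = rank_candidates(assign_tiers([a, b]))
        assert ranked[0].variant.rsid == "rs_b"

    def test_position_is_the_final_deterministic_tiebreak(self):
        a = make_record("rs_late", pos=500)
        b = make_record("rs_early", pos=100)
        ranked = rank_candidates(assign_tiers([a, b]))
        assert [r.variant.rsid for r in ranked] == ["rs_early", "rs_late"]

    def test_ranking_is_permutation_invariant(self):
        rng = np.random.default_rng(0)
        recs = [make_record(f"rs{i}", pos=100 + i, r2=float(rng.uniform(0.81, 1.0)),
                            n_tf=int(rng.integers(0, 3)),
                            flagged_delta=float(-rng.uniform(2, 5)))
                for i in range(12)]
        assign_tiers(recs)
        baseline = [r.variant.rsid for r in rank_candidates(list(recs))]
        for _ in range(5):
            shuffled = list(recs)
            rng.shuffle(shuffled)
            assert [r.variant.rsid for r in rank_candidates(shuffled)] == baseline

    def test_composite_score_reflects_tier_and_delta(self):
        (rec,) = rank_candidates(assign_tiers([make_record(flagged_delta=-3.0)]))
        assert rec.composite_score == pytest.approx(4 + 0.5 * np.tanh(3.0 / 4.0))


def test_records_to_dataframe_carries_the_audit_columns():
    recs = rank_candidates(assign_tiers([make_record(flagged_delta=-2.5)]))
    df = records_to_dataframe(recs)
    assert df.loc[0, "tier"] == 4
    assert df.loc[0, "flagged_motifs"] == "CEBPB"
    assert df.loc[0, "max_abs_delta"] == pytest.approx(2.5)
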