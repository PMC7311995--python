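"""Classifier formulas, hierarchical ranking and CSV output."""

import csv
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comsel import (
    BasePair,
    CoMCandidate,
    CombinationEnergies,
    HelixContext,
    Interaction,
    RankingConfig,
    e_classifier,
    evaluate_combinations,
    mfe_cover,
    min_delta_e,
    rank_candidates,
    rank_pair,
    write_results_csv,
)
from comsel.errors import InvalidInputError
from comsel.ranking import CSV_COLUMNS


def interaction_at(pairs, e_total):
    bps = tuple(BasePair(*p) for p in pairs)
    return Interaction(pairs=bps, e_hybrid=e_total, ed_a=0.0, ed_b=0.0, e_total=e_total)


def combo(ww=None, wm=None, mw=None, mm=None, mm_pairs=None):
    """CombinationEnergies with single-pair stand-in interactions."""

    def make(e, pairs=None):
        if e is None:
            return None
        return interaction_at(pairs or [(0, 0, "G", "C")], e)

    return CombinationEnergies(
        ww=make(ww), wm=make(wm), mw=make(mw), mm=make(mm, mm_pairs)
    )


GC_CANDIDATE = CoMCandidate(
    wildtype=BasePair(1, 1, "G", "C"),
    mutant_nt_a="C",
    mutant_nt_b="G",
    context=HelixContext.STACKED_BOTH,
)


class TestEClassifier:
    def test_pass_case(self):
        en = combo(ww=-10, mm=-9, wm=-7, mw=-6.5)
        assert e_classifier(en, 2, 1) == (True, None)

    def test_fail_on_alpha_margin(self):
        en = combo(ww=-10, mm=-9, wm=-8.5, mw=-9.5)
        passed, reason = e_classifier(en, 2, 1)
        assert not passed
        assert "alpha" in reason

    def test_unfavorable_wildtype_fails_regardless(self):
        en = combo(ww=None, mm=-9, wm=-1, mw=-1)
        passed, reason = e_classifier(en, 2, 1)
        assert not passed
        assert "wildtype-only" in reason

    def test_none_mixed_counts_as_zero(self):
        en = combo(ww=-10, mm=-9, wm=None, mw=-4)
        # min(0, -4) = -4; -10 + 2 < -4 and -9 + 1 < -4 -> pass
        assert e_classifier(en, 2, 1)[0]

    def test_negative_thresholds_rejected(self):
        with pytest.raises(InvalidInputError):
            e_classifier(combo(ww=-1, mm=-1, wm=-1, mw=-1), -1, 0)


class TestMinDeltaE:
    @pytest.mark.parametrize(
        "ww,mm,wm,mw,expected",
        [
            (-10, -9, -7, -6, 2.0),
            (-5, -5, -5, -5, 0.0),
            (-10, -9, None, -4, 5.0),  # none-flagged wm enters as 0
        ],
    )
    def test_formula(self, ww, mm, wm, mw, expected):
        assert min_delta_e(combo(ww=ww, mm=mm, wm=wm, mw=mw)) == pytest.approx(expected)


class TestMfeCover:
    def test_pair_present(self):
        cand = CoMCandidate(
            wildtype=BasePair(10, 20, "G", "C"),
            mutant_nt_a="C",
            mutant_nt_b="G",
            context=HelixContext.STACKED_BOTH,
        )
        en = combo(mm=-5, mm_pairs=[(9, 21, "A", "U"), (10, 20, "C", "G")])
        assert mfe_cover(cand, en)

    def test_absent_interaction(self):
        assert not mfe_cover(GC_CANDIDATE, combo(mm=None))

    def test_positions_paired_with_other_partners(self):
        # mm interaction spans the mutated positions but pairs them elsewhere
        cand = CoMCandidate(
            wildtype=BasePair(1, 1, "G", "C"),
            mutant_nt_a="C",
            mutant_nt_b="G",
            context=HelixContext.STACKED_BOTH,
        )
        en = combo(mm=-5, mm_pairs=[(0, 2, "G", "C"), (1, 0, "C", "G")])
        assert not mfe_cover(cand, en)


@settings(derandomize=True, max_examples=200)
@given(
    energies=st.tuples(*[st.one_of(st.none(), st.floats(-20, 3)) for _ in range(4)]),
    alpha=st.floats(0, 5),
    beta=st.floats(0, 5),
)
def test_classifier_formulas_match_direct_evaluation(energies, alpha, beta):
    ww, wm, mw, mm = energies
    en = combo(ww=ww, wm=wm, mw=mw, mm=mm)
    e_ww = 0.0 if ww is None else ww
    e_wm = 0.0 if wm is None else wm
    e_mw = 0.0 if mw is None else mw
    e_mm = 0.0 if mm is None else mm
    expected = (
        e_ww < 0
        and e_mm < 0
        and e_ww + alpha < min(e_mw, e_wm)
        and e_mm + beta < min(e_mw, e_wm)
    )
    assert e_classifier(en, alpha, beta)[0] == expected
    assert min_delta_e(en) == pytest.approx(min(e_mw, e_wm) - max(e_ww, e_mm))


def make_candidate(pos_a, pos_b=None, wt=("G", "C")):
    pos_b = pos_a if pos_b is None else pos_b
    return CoMCandidate(
        wildtype=BasePair(pos_a, pos_b, *wt),
        mutant_nt_a=wt[1],
        mutant_nt_b=wt[0],
        context=HelixContext.STACKED_BOTH,
    )


class TestRankCandidates:
    def test_stratum_dominates_mindeltae(self):
        passing = combo(ww=-10, mm=-10, wm=-5, mw=-5,
                        mm_pairs=[(1, 1, "C", "G")])
        failing_e = combo(ww=-10, mm=-10, wm=-9.5, mw=-9.5,
                          mm_pairs=[(2, 2, "C", "G")])
        ranked = rank_candidates(
            [(make_candidate(2), failing_e), (make_candidate(1), passing)],
            RankingConfig(),
        )
        assert [rc.candidate.wildtype.pos_a for rc in ranked] == [1, 2]
        assert ranked[0].stratum == 2 and ranked[1].stratum == 1
        assert [rc.rank for rc in ranked] == [1, 2]

    def test_mindeltae_orders_within_stratum(self):
        big = combo(ww=-10, mm=-10, wm=-7, mw=-7, mm_pairs=[(1, 1, "C", "G")])
        small = combo(ww=-10, mm=-10, wm=-8.5, mw=-8.5, mm_pairs=[(2, 2, "C", "G")])
        ranked = rank_candidates(
            [(make_candidate(2), small), (make_candidate(1), big)], RankingConfig()
        )
        assert [rc.min_delta_e for rc in ranked] == [3.0, 1.5]

    def test_full_tie_breaks_by_position_then_mutant(self):
        en = lambda pos: combo(ww=-10, mm=-10, wm=-6, mw=-6,
                               mm_pairs=[(pos, pos, "C", "G")])
        ranked = rank_candidates(
            [(make_candidate(5), en(5)), (make_candidate(2), en(2))], RankingConfig()
        )
        assert [rc.candidate.wildtype.pos_a for rc in ranked] == [2, 5]

    def test_ranks_are_permutation(self):
        rng = random.Random(3)
        evaluated = []
        for pos in range(8):
            e = combo(ww=-rng.uniform(5, 15), mm=-rng.uniform(5, 15),
                      wm=-rng.uniform(0, 10), mw=-rng.uniform(0, 10),
                      mm_pairs=[(pos, pos, "C", "G")])
            evaluated.append((make_candidate(pos), e))
        ranked = rank_candidates(evaluated, RankingConfig())
        assert sorted(rc.rank for rc in ranked) == list(range(1, 9))
        # within equal stratum minDeltaE must be non-increasing with rank
        by_stratum = {}
        for rc in sorted(ranked, key=lambda r: r.rank):
            by_stratum.setdefault(rc.stratum, []).append(rc.min_delta_e)
        for values in by_stratum.values():
            assert values == sorted(values, reverse=True)


class TestEvaluateCombinations:
    def test_ww_independent_of_candidate(self, oracle_scale_fixture, predictor):
        fx = oracle_scale_fixture
        ranked = rank_pair(fx.seq_a, fx.seq_b, predictor)
        ww_values = {rc.energies.mfe_ww for rc in ranked}
        assert len(ww_values) == 1

    def test_degenerate_identity_mutation_equalizes(self, predictor, gggg_ccccc):
        # bypass candidate invariants: identical 'mutants' must reproduce ww
        a, b = gggg_ccccc
        cand = CoMCandidate.__new__(CoMCandidate)
        object.__setattr__(cand, "wildtype", BasePair(2, 2, "G", "C"))
        object.__setattr__(cand, "mutant_nt_a", "G")
        object.__setattr__(cand, "mutant_nt_b", "C")
        object.__setattr__(cand, "context", HelixContext.STACKED_BOTH)
        object.__setattr__(cand, "source_rank", 1)
        en = evaluate_combinations(a, b, cand, predictor)
        assert en.mfe_ww == en.mfe_wm == en.mfe_mw == en.mfe_mm
        assert min_delta_e(en) == pytest.approx(0.0)
        for alpha, beta in ((0.5, 0.5), (2, 1)):
            assert not e_classifier(en, alpha, beta)[0]


class TestMonotonicity:
    def test_valid_set_shrinks_with_alpha_beta(self):
        rng = random.Random(5)
        combos = [
            combo(ww=-rng.uniform(0, 15), mm=-rng.uniform(0, 15),
                  wm=-rng.uniform(0, 12), mw=-rng.uniform(0, 12))
            for _ in range(200)
        ]
        grid = [0.0, 0.5, 1.0, 2.0, 4.0]
        for beta in grid:
            previous = None
            for alpha in grid:
                valid = {i for i, en in enumerate(combos)
                         if e_classifier(en, alpha, beta)[0]}
                if previous is not None:
                    assert valid <= previous
                previous = valid


class TestCsvOutput:
    def test_empty_list_writes_header_only(self, tmp_path):
        out = tmp_path / "empty.csv"
        write_results_csv([], out)
        rows = list(csv.reader(out.open()))
        assert rows == [CSV_COLUMNS]

    def test_roundtrip(self, tmp_path, oracle_scale_fixture, predictor):
        fx = oracle_scale_fixture
        ranked = rank_pair(fx.seq_a, fx.seq_b, predictor)
        assert ranked
        out = tmp_path / "ranked.csv"
        write_results_csv(ranked, out)
        with out.open() as handle:
            rows = list(csv.DictReader(handle))
        assert [int(r["rank"]) for r in rows] == list(range(1, len(ranked) + 1))
        for row, rc in zip(rows, ranked):
            assert int(row["pos_a_1based"]) == rc.candidate.wildtype.pos_a + 1
            assert int(row["pos_b_1based"]) == rc.candidate.wildtype.pos_b + 1
            assert row["wt_bp"] == rc.candidate.wildtype.bp_type
            assert row["mut_bp"] == rc.candidate.mutant_nt_a + rc.candidate.mutant_nt_b
            assert float(row["mfe_ww"]) == pytest.approx(rc.energies.mfe_ww, abs=0.005)
            assert float(row["minDeltaE"]) == pytest.approx(rc.min_delta_e, abs=0.005)
            assert row["mfeCover"] == str(rc.mfe_cover_pass)
            assert row["E_pass"] == str(rc.e_pass)


class TestRankingConfigValidation:
    def test_negative_alpha_rejected(self):
        with pytest.raises(InvalidInputError):
            RankingConfig(alpha=-1)

    def test_duplicate_chain_rejected(self):
        with pytest.raises(InvalidInputError):
            RankingConfig(classifier_chain=("E", "E"))

    def test_unknown_sorter_rejected(self):
        with pytest.raises(InvalidInputError):
            RankingConfig(sorter="bogus")
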