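"""Benchmark harness: type tally, CoM rank, profiling, sweeps, comparisons."""

import numpy as np
import pandas as pd
import pytest

from comsel import (
    BasePair,
    Interaction,
    KnownCoM,
    KnownCoMRecord,
    RankingConfig,
    RnaSequence,
    alpha_beta_sweep,
    com_rri_rank,
    energy_profile,
    generate_known_com_table,
    mutation_type_class,
    ranking_comparison,
    read_known_com_table,
)
from comsel.errors import InvalidInputError


def inter(pairs, e_total):
    return Interaction(
        pairs=tuple(BasePair(*p) for p in pairs),
        e_hybrid=e_total, ed_a=0.0, ed_b=0.0, e_total=e_total,
    )


class StubPredictor:
    """Serves handcrafted interactions keyed by residue strings."""

    def __init__(self, mfe_table, subopt_table=None):
        self._mfe = mfe_table
        self._sub = subopt_table or {}

    def mfe(self, a, b, region=None):
        return self._mfe[(a.residues, b.residues)]

    def suboptimals(self, a, b, max_count, region=None):
        return self._sub[(a.residues, b.residues)][:max_count]


class TestMutationTypeClass:
    @pytest.mark.parametrize(
        "wt,mut,expected",
        [
            ("AU", "CG", "AUCG"),
            ("UA", "GC", "AUCG"),  # lex-sorting merges orientations
            ("GC", "CG", "CGCG"),
        ],
    )
    def test_examples(self, wt, mut, expected):
        assert mutation_type_class(wt, mut) == expected

    def test_swap_invariance(self):
        from comsel.sequence import PAIRABLE

        for (a1, b1) in PAIRABLE:
            for (a2, b2) in PAIRABLE:
                assert mutation_type_class(a1 + b1, a2 + b2) == mutation_type_class(
                    b1 + a1, b2 + a2
                )

    def test_rejects_unpairable(self):
        with pytest.raises(InvalidInputError):
            mutation_type_class("AG", "CG")


def stub_record():
    return KnownCoMRecord(
        pair_id="stub",
        seq_a=RnaSequence("stub_A", "AGA"),
        seq_b=RnaSequence("stub_B", "UCU"),
        coms=(KnownCoM(pos_a=1, pos_b=1, wt_bp="GC", mut_bp="CG"),),
    )


class TestComRriRank:
    def test_pair_in_mfe_is_rank_one(self, predictor):
        parsed = read_known_com_table_from_generated(3, seed=21)
        assert [com_rri_rank(rec, predictor) for rec in parsed] == [1, 1, 1]

    def test_pair_only_in_second_interaction(self):
        record = stub_record()
        first = inter([(0, 2, "A", "U"), (2, 0, "A", "U")], -9.0)
        second = inter([(1, 1, "G", "C")], -5.0)
        stub = StubPredictor({}, {("AGA", "UCU"): [first, second]})
        assert com_rri_rank(record, stub) == 2

    def test_absent_pair_returns_none(self):
        record = stub_record()
        only = inter([(0, 2, "A", "U")], -3.0)
        stub = StubPredictor({}, {("AGA", "UCU"): [only]})
        assert com_rri_rank(record, stub) is None


def single_gc_stub(ww=-8.0, wm=-6.5, mw=-6.0, mm=-8.0):
    """One record whose MFE has a single GC pair; mutant energies handcrafted.

    min(wm, mw) - ww = 1.5 by default: the known CoM is E-valid at alpha=1
    and invalid at alpha=2 (beta permitting).
    """
    record = stub_record()
    table = {
        ("AGA", "UCU"): inter(
            [(0, 2, "A", "U"), (1, 1, "G", "C"), (2, 0, "A", "U")], ww
        ),
        ("AGA", "UGU"): inter([(0, 2, "A", "U")], wm),
        ("ACA", "UCU"): inter([(0, 2, "A", "U")], mw),
        ("ACA", "UGU"): inter(
            [(0, 2, "A", "U"), (1, 1, "C", "G"), (2, 0, "A", "U")], mm
        ),
    }
    return record, StubPredictor(table)


class TestAlphaBetaSweep:
    def test_threshold_boundary_from_constructed_energies(self):
        record, stub = single_gc_stub()
        result = alpha_beta_sweep([record], stub, alphas=[1.0, 2.0], betas=[1.0])
        t = result.table.set_index("alpha")
        assert t.loc[1.0, "count"] == 1 and not t.loc[1.0, "known_fails"]
        assert np.isnan(t.loc[2.0, "count"]) and t.loc[2.0, "known_fails"]

    def test_counts_monotone_in_alpha_and_beta(self, predictor):
        records = read_known_com_table_from_generated(6, seed=31)
        grid = [0.5, 1.0, 2.0, 3.0]
        result = alpha_beta_sweep(records, predictor, grid, grid)
        wide = result.table.pivot_table(
            index="pair_id", columns=["alpha", "beta"], values="count"
        )
        for pair_id, row in wide.iterrows():
            for b in grid:
                counts = [row.get((a, b), np.nan) for a in grid]
                seen = [c for c in counts if not np.isnan(c)]
                assert seen == sorted(seen, reverse=True) or all(
                    x >= y for x, y in zip(seen, seen[1:])
                )

    def test_empty_grid_rejected(self, predictor):
        with pytest.raises(InvalidInputError):
            alpha_beta_sweep([], predictor, [], [1.0])


def read_known_com_table_from_generated(n, seed):
    rows = generate_known_com_table(n, seed=seed)
    return [
        KnownCoMRecord(
            pair_id=r["pair_id"],
            seq_a=RnaSequence(r["pair_id"] + "_A", r["seq_a"]),
            seq_b=RnaSequence(r["pair_id"] + "_B", r["seq_b"]),
            coms=(KnownCoM(r["pos_a"] - 1, r["pos_b"] - 1, r["wt_bp"], r["mut_bp"]),),
        )
        for r in rows
    ]


class TestEnergyProfile:
    def test_background_is_other_gc_pairs_of_mfe(self, predictor):
        records = read_known_com_table_from_generated(4, seed=17)
        profile, _ = energy_profile(records, predictor)
        for rec in records:
            sub = profile[profile["pair_id"] == rec.pair_id]
            mfe = predictor.mfe(rec.seq_a, rec.seq_b)
            n_gc = sum(1 for bp in mfe.pairs if {bp.nt_a, bp.nt_b} == {"G", "C"})
            assert len(sub) == n_gc
            assert (sub["group"] == "known").sum() == 1

    def test_identical_columns_give_zero_differences(self):
        record, stub = single_gc_stub(ww=-7, wm=-7, mw=-7, mm=-7)
        profile, tests = energy_profile([record], stub)
        assert profile["wm_ww"].eq(0).all()
        assert profile["minDeltaE"].eq(0).all()
        # single observation per group: p-values must be flagged unavailable
        assert tests["p_value"].isna().all()

    def test_welch_p_matches_direct_formula(self, predictor):
        records = read_known_com_table_from_generated(6, seed=23)
        profile, tests = energy_profile(records, predictor)
        known = profile[profile["group"] == "known"]["mm"].to_numpy()
        bg = profile[profile["group"] == "background"]["mm"].to_numpy()
        # Welch statistic with Satterthwaite degrees of freedom, by hand
        v1, v2 = known.var(ddof=1), bg.var(ddof=1)
        n1, n2 = len(known), len(bg)
        t = (known.mean() - bg.mean()) / np.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
        from scipy.stats import t as tdist

        expected = 2 * tdist.sf(abs(t), df)
        got = tests.query(
            "test == 'welch_known_vs_background' and column == 'mm'"
        )["p_value"].iloc[0]
        assert got == pytest.approx(expected, abs=1e-10)


class TestRankingComparison:
    def test_empty_chain_counts_equal_mindeltae_rank(self):
        record, stub = single_gc_stub()
        df = ranking_comparison(
            [record], stub, {"sort_only": RankingConfig(classifier_chain=())}
        )
        assert df["count"].iloc[0] == 1
        assert not df["known_fails"].iloc[0]

    def test_adding_classifier_never_increases_count_when_known_valid(self, predictor):
        records = read_known_com_table_from_generated(6, seed=29)
        configs = {
            "sort_only": RankingConfig(classifier_chain=()),
            "with_E": RankingConfig(classifier_chain=("E",)),
        }
        df = ranking_comparison(records, predictor, configs).pivot(
            index="pair_id", columns="config", values="count"
        )
        for _, row in df.iterrows():
            if not np.isnan(row["with_E"]):
                assert row["with_E"] <= row["sort_only"]

    def test_identical_configs_identical_output(self, predictor):
        records = read_known_com_table_from_generated(3, seed=37)
        config = RankingConfig()
        df = ranking_comparison(records, predictor, {"a": config, "b": config})
        a = df[df["config"] == "a"].drop(columns="config").reset_index(drop=True)
        b = df[df["config"] == "b"].drop(columns="config").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


class TestKnownComTableValidation:
    def test_wildtype_mismatch_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame(
            [
                {
                    "pair_id": "x", "seq_a": "AGA", "seq_b": "UCU",
                    "pos_a": 2, "pos_b": 2, "wt_bp": "CG", "mut_bp": "GC",
                }
            ]
        ).to_csv(path, index=False)
        with pytest.raises(InvalidInputError, match="does not match"):
            read_known_com_table(path)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "cols.csv"
        pd.DataFrame([{"pair_id": "x"}]).to_csv(path, index=False)
        with pytest.raises(InvalidInputError, match="missing columns"):
            read_known_com_table(path)
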