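"""Evaluation harness over tables of known compensatory mutations.

Given records of (sequence pair, experimentally used CoM), the harness
reproduces the analyses used to justify the default ranking: mutation-type
tallies, the rank of the interaction containing the known CoM, energy
profiling of known vs background GC flips with t-tests, alpha/beta
threshold sweeps, and classifier/sorter comparisons.  All outputs are tidy
pandas tables; plotting is left to the user.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence as Seq

import numpy as np
import pandas as pd
from scipy import stats

from .candidates import CoMCandidate, HelixContext, classify_context
from .errors import InvalidInputError
from .interactions import BasePair, Interaction
from .ranking import (
    CombinationEnergies,
    RankingConfig,
    e_classifier,
    evaluate_combinations,
    min_delta_e,
    rank_candidates,
)
from .sequence import RnaSequence, is_pairable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KnownCoM:
    """One known compensatory base-pair mutation (0-based positions)."""

    pos_a: int
    pos_b: int
    wt_bp: str
    mut_bp: str

    def __post_init__(self) -> None:
        if not is_pairable(self.wt_bp[0], self.wt_bp[1]):
            raise InvalidInputError(f"wildtype pair {self.wt_bp} not pairable")
        # reuse the candidate invariants (pairable mutant, non-compatibility)
        CoMCandidate(
            wildtype=BasePair(self.pos_a, self.pos_b, self.wt_bp[0], self.wt_bp[1]),
            mutant_nt_a=self.mut_bp[0],
            mutant_nt_b=self.mut_bp[1],
            context=HelixContext.STACKED_BOTH,
        )


@dataclass(frozen=True)
class KnownCoMRecord:
    pair_id: str
    seq_a: RnaSequence
    seq_b: RnaSequence
    coms: tuple[KnownCoM, ...]

    def __post_init__(self) -> None:
        if not self.coms:
            raise InvalidInputError(f"record {self.pair_id}: no CoM entries")
        for com in self.coms:
            for pos, seq, nt in (
                (com.pos_a, self.seq_a, com.wt_bp[0]),
                (com.pos_b, self.seq_b, com.wt_bp[1]),
            ):
                if not 0 <= pos < len(seq):
                    raise InvalidInputError(
                        f"record {self.pair_id}: CoM position {pos} out of range"
                    )
                if seq.residues[pos] != nt:
                    raise InvalidInputError(
                        f"record {self.pair_id}: wildtype {nt} does not match "
                        f"sequence residue {seq.residues[pos]} at {pos}"
                    )


def read_known_com_table(path: str | Path) -> list[KnownCoMRecord]:
    """Read the benchmark CSV (pair_id, seq_a, seq_b, pos_a, pos_b, wt_bp,
    mut_bp; 1-based coordinates).  Rows sharing a pair_id are grouped into
    one record with several CoM entries."""
    df = pd.read_csv(path, dtype=str)
    required = {"pair_id", "seq_a", "seq_b", "pos_a", "pos_b", "wt_bp", "mut_bp"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for pair_id, group in df.groupby("pair_id", sort=False):
        seqs_a = group["seq_a"].unique()
        seqs_b = group["seq_b"].unique()
        if len(seqs_a) != 1 or len(seqs_b) != 1:
            raise InvalidInputError(
                f"{path}: record {pair_id} mixes different sequences"
            )
        coms = tuple(
            KnownCoM(
                pos_a=int(row.pos_a) - 1,
                pos_b=int(row.pos_b) - 1,
                wt_bp=row.wt_bp,
                mut_bp=row.mut_bp,
            )
            for row in group.itertuples()
        )
        records.append(
            KnownCoMRecord(
                pair_id=str(pair_id),
                seq_a=RnaSequence.from_raw(f"{pair_id}_A", seqs_a[0]),
                seq_b=RnaSequence.from_raw(f"{pair_id}_B", seqs_b[0]),
                coms=coms,
            )
        )
    return records


def mutation_type_class(wt_bp: str, mut_bp: str) -> str:
    """Lex-sorted mutation-type label, e.g. (AU -> CG) and (UA -> GC)
    both map to 'AUCG'."""
    for bp in (wt_bp, mut_bp):
        if not is_pairable(bp[0], bp[1]):
            raise InvalidInputError(f"{bp} is not a pairable base pair")
    return "".join(sorted(wt_bp)) + "".join(sorted(mut_bp))


def mutation_type_tally(records: Seq[KnownCoMRecord]) -> pd.Series:
    """Counts of mutation-type classes over all CoM entries."""
    classes = [
        mutation_type_class(com.wt_bp, com.mut_bp)
        for rec in records
        for com in rec.coms
    ]
    return pd.Series(classes, dtype=str).value_counts().sort_index()


def com_rri_rank(
    record: KnownCoMRecord, predictor, max_subopt: int = 100
) -> Optional[int]:
    """1-based rank of the first energy-sorted interaction containing at
    least one of the record's CoM base pairs; None if absent within
    ``max_subopt`` suboptimals."""
    if max_subopt < 1:
        raise InvalidInputError("max_subopt must be >= 1")
    wanted = {(com.pos_a, com.pos_b) for com in record.coms}
    for rank, inter in enumerate(
        predictor.suboptimals(record.seq_a, record.seq_b, max_count=max_subopt),
        start=1,
    ):
        if wanted & inter.pair_positions():
            return rank
    return None


# ---------------------------------------------------------------------------
# GC-flip candidate machinery shared by the profiling / sweep analyses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _FlipSet:
    """Evaluated GC-flip candidates of one record's MFE interaction."""

    record: KnownCoMRecord
    mfe: Optional[Interaction]
    candidates: tuple[CoMCandidate, ...]
    energies: tuple[CombinationEnergies, ...]
    known_index: Optional[int]  # index into candidates, None if not generated


def _gc_flip_candidates(
    record: KnownCoMRecord, predictor, bp_classes: frozenset[str] = frozenset({"CG"})
) -> _FlipSet:
    """Flip candidates for all MFE base pairs of the given classes.

    Energies are evaluated once per candidate and reused by every analysis
    (threshold sweeps only re-apply the classifier arithmetic).
    """
    mfe = predictor.mfe(record.seq_a, record.seq_b)
    if mfe is None:
        return _FlipSet(record, None, (), (), None)
    cands = []
    for bp in mfe.pairs:
        if "".join(sorted((bp.nt_a, bp.nt_b))) not in bp_classes:
            continue
        cands.append(
            CoMCandidate(
                wildtype=bp,
                mutant_nt_a=bp.nt_b,
                mutant_nt_b=bp.nt_a,
                context=classify_context(mfe, bp),
            )
        )
    energies = tuple(
        evaluate_combinations(record.seq_a, record.seq_b, cand, predictor, ww=mfe)
        for cand in cands
    )
    known_index = None
    for i, cand in enumerate(cands):
        for com in record.coms:
            if (cand.wildtype.pos_a, cand.wildtype.pos_b) == (com.pos_a, com.pos_b) and (
                cand.mutant_nt_a + cand.mutant_nt_b == com.mut_bp
            ):
                known_index = i
                break
        if known_index is not None:
            break
    return _FlipSet(record, mfe, tuple(cands), energies, known_index)


_DIFF_COLUMNS = ["wm_ww", "mw_ww", "mm_ww", "wm_mm", "mw_mm"]


def energy_profile(
    records: Seq[KnownCoMRecord], predictor
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Energy profiling of known GC-flip CoMs against a background model.

    For every record whose MFE interaction contains the known CoM pair, the
    known CoM is one observation of the 'known' group and every *other* GC
    pair of the MFE interaction, treated as a flipped CGCG mutation, joins
    the 'background' group.  Returns (profile, tests):

    profile
        one row per observation: the four combination MFEs, the five
        pairwise differences (wm-ww, mw-ww, mm-ww, wm-mm, mw-mm) and
        minDeltaE.
    tests
        Welch two-sample p-values (known vs background, per combination
        column; two-tailed, unequal variance, unpaired) and paired t-test
        p-values per difference column within each group.  Groups with
        fewer than two observations yield NaN p-values.
    """
    rows = []
    for record in records:
        fs = _gc_flip_candidates(record, predictor)
        for i, (cand, en) in enumerate(zip(fs.candidates, fs.energies)):
            group = "known" if i == fs.known_index else "background"
            row = {
                "pair_id": record.pair_id,
                "group": group,
                "pos_a": cand.wildtype.pos_a + 1,
                "pos_b": cand.wildtype.pos_b + 1,
                "ww": en.mfe_ww,
                "wm": en.mfe_wm,
                "mw": en.mfe_mw,
                "mm": en.mfe_mm,
            }
            row["wm_ww"] = row["wm"] - row["ww"]
            row["mw_ww"] = row["mw"] - row["ww"]
            row["mm_ww"] = row["mm"] - row["ww"]
            row["wm_mm"] = row["wm"] - row["mm"]
            row["mw_mm"] = row["mw"] - row["mm"]
            row["minDeltaE"] = min_delta_e(en)
            rows.append(row)
    profile = pd.DataFrame(rows)

    tests = []
    if not profile.empty:
        known = profile[profile["group"] == "known"]
        background = profile[profile["group"] == "background"]
        for col in ["ww", "wm", "mw", "mm", "minDeltaE"]:
            p = np.nan
            if len(known) >= 2 and len(background) >= 2:
                p = stats.ttest_ind(
                    known[col], background[col], equal_var=False
                ).pvalue
            tests.append(
                {"test": "welch_known_vs_background", "column": col, "group": "both",
                 "p_value": p}
            )
        for group_name, group in (("known", known), ("background", background)):
            for col in _DIFF_COLUMNS:
                ref = col.split("_")[1]
                other = col.split("_")[0]
                p = np.nan
                if len(group) >= 2:
                    p = stats.ttest_rel(group[other], group[ref]).pvalue
                tests.append(
                    {"test": "paired_vs_" + ref, "column": col,
                     "group": group_name, "p_value": p}
                )
    return profile, pd.DataFrame(tests)


@dataclass(frozen=True)
class SweepResult:
    """alpha/beta sweep outcome.

    table: long per-(alpha, beta, pair) rows with the count of valid
    candidates ranked not worse than the known CoM (NaN when the known CoM
    fails the constraints, with ``known_fails`` True).  summary: per grid
    cell the mean count over non-failing records and the failure count.
    """

    table: pd.DataFrame
    summary: pd.DataFrame


def _valid_count(
    fs: _FlipSet, alpha: float, beta: float
) -> tuple[Optional[int], bool]:
    """(count of E-valid candidates ranked not worse than the known CoM,
    known-CoM-fails flag) for one record at one threshold pair."""
    if fs.known_index is None:
        return None, True
    valid = [
        (min_delta_e(en), cand.wildtype.pos_a, i)
        for i, (cand, en) in enumerate(zip(fs.candidates, fs.energies))
        if e_classifier(en, alpha, beta)[0]
    ]
    known = [v for v in valid if v[2] == fs.known_index]
    if not known:
        return None, True
    valid.sort(key=lambda v: (-v[0], v[1]))
    rank = valid.index(known[0]) + 1
    return rank, False


def alpha_beta_sweep(
    records: Seq[KnownCoMRecord],
    predictor,
    alphas: Seq[float],
    betas: Seq[float],
) -> SweepResult:
    """Sweep the E-classifier thresholds over a grid.

    Candidate generation is restricted to flips of the MFE interactions' GC
    base pairs; combination energies are computed once per candidate and
    shared across the grid.  Records whose known CoM is not generated or
    fails E(alpha, beta) are excluded from the cell mean and counted as
    failures.
    """
    if not alphas or not betas:
        raise InvalidInputError("alpha and beta grids must be non-empty")
    flip_sets = [_gc_flip_candidates(r, predictor) for r in records]
    rows = []
    for alpha in alphas:
        for beta in betas:
            for fs in flip_sets:
                count, fails = _valid_count(fs, alpha, beta)
                rows.append(
                    {
                        "alpha": alpha,
                        "beta": beta,
                        "pair_id": fs.record.pair_id,
                        "count": np.nan if count is None else count,
                        "known_fails": fails,
                    }
                )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby(["alpha", "beta"])
        .agg(
            mean_count=("count", "mean"),
            n_known_failing=("known_fails", "sum"),
            n_records=("pair_id", "count"),
        )
        .reset_index()
    )
    return SweepResult(table=table, summary=summary)


def ranking_comparison(
    records: Seq[KnownCoMRecord],
    predictor,
    configs: dict[str, RankingConfig],
) -> pd.DataFrame:
    """Compare classifier/sorter combinations on shared GC-flip candidates.

    All configs are applied to the same candidate set (flips of the MFE
    GC pairs, energies computed once).  For each config and record, the
    count of candidates ranked not worse than the known CoM is reported
    when the known CoM is valid under the config's full chain (all chain
    classifiers pass); otherwise the record counts as a failure.
    """
    flip_sets = [_gc_flip_candidates(r, predictor) for r in records]
    rows = []
    for name, config in configs.items():
        for fs in flip_sets:
            count: Optional[int] = None
            fails = True
            if fs.known_index is not None:
                ranked = rank_candidates(
                    list(zip(fs.candidates, fs.energies)), config
                )
                by_identity = {
                    rc.candidate.identity: rc for rc in ranked
                }
                known_rc = by_identity[fs.candidates[fs.known_index].identity]
                if known_rc.stratum == len(config.classifier_chain):
                    fails = False
                    count = sum(
                        1
                        for rc in ranked
                        if rc.stratum == len(config.classifier_chain)
                        and rc.rank <= known_rc.rank
                    )
            rows.append(
                {
                    "config": name,
                    "pair_id": fs.record.pair_id,
                    "count": np.nan if count is None else count,
                    "known_fails": fails,
                }
            )
    return pd.DataFrame(rows)
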