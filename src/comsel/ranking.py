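"""Four-combination evaluation and hierarchical ranking of CoM candidates.

Every candidate is evaluated on the four wildtype/mutant sequence
combinations (ww, wm, mw, mm; first letter = sequence A state).  Candidates
then pass through an ordered classifier chain:

mfeCover
    the mutated base pair must be present in the mutant-only (mm) MFE
    interaction — otherwise the mutant interaction formed elsewhere or not
    at all.  This is the strict base-pair-presence reading; site-coverage
    of the mutated positions alone does not pass.
E
    MFE(ww) < 0, MFE(mm) < 0, MFE(ww) + alpha < min(MFE(mw), MFE(wm)) and
    MFE(mm) + beta < min(MFE(mw), MFE(wm)) (strict inequalities).

Candidates are ordered by how long a prefix of the chain they satisfy
(their stratum), then by the minDeltaE statistic

    minDeltaE = min(MFE(mw), MFE(wm)) - max(MFE(ww), MFE(mm))

descending: larger values mean both mixed combinations are destabilized
more strongly.  An absent favorable interaction enters the arithmetic as
energy 0 (and fails the below-zero requirements), flagged explicitly in
the output.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Optional, Sequence as Seq

from .candidates import (
    CandidateFilters,
    CoMCandidate,
    CollectionMode,
    MutationMode,
    collect_basepairs,
    filter_basepairs,
    generate_candidates,
)
from .errors import InvalidInputError, PredictionError
from .interactions import Interaction
from .sequence import RnaSequence, apply_mutation

logger = logging.getLogger(__name__)

COMBINATIONS = ("ww", "wm", "mw", "mm")

CLASSIFIERS = ("mfeCover", "E")


@dataclass(frozen=True)
class CombinationEnergies:
    """MFE interactions (or None) for the four sequence combinations.

    ``energy(combo)`` returns the interaction's e_total, or 0.0 when no
    favorable interaction exists (the explicit none encoding).
    """

    ww: Optional[Interaction]
    wm: Optional[Interaction]
    mw: Optional[Interaction]
    mm: Optional[Interaction]

    def interaction(self, combo: str) -> Optional[Interaction]:
        if combo not in COMBINATIONS:
            raise InvalidInputError(f"unknown combination {combo!r}")
        return getattr(self, combo)

    def energy(self, combo: str) -> float:
        inter = self.interaction(combo)
        return inter.e_total if inter is not None else 0.0

    def is_none(self, combo: str) -> bool:
        return self.interaction(combo) is None

    @property
    def mfe_ww(self) -> float:
        return self.energy("ww")

    @property
    def mfe_wm(self) -> float:
        return self.energy("wm")

    @property
    def mfe_mw(self) -> float:
        return self.energy("mw")

    @property
    def mfe_mm(self) -> float:
        return self.energy("mm")


@dataclass(frozen=True)
class RankingConfig:
    """Classifier chain, thresholds and candidate-generation settings.

    Defaults follow the recommended setup: chain mfeCover then E with
    alpha=2, beta=1 kcal/mol, minDeltaE sorting, nucleotide-flip mutations
    generated from the MFE interaction's pairs, lonely pairs excluded.
    """

    alpha: float = 2.0
    beta: float = 1.0
    classifier_chain: tuple[str, ...] = ("mfeCover", "E")
    sorter: str = "minDeltaE"
    mutation_mode: MutationMode = MutationMode.FLIP
    collection_mode: CollectionMode = CollectionMode.MFE_ONLY
    filters: CandidateFilters = field(default_factory=CandidateFilters)
    max_subopt: int = 20

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise InvalidInputError("alpha and beta must be >= 0")
        if len(set(self.classifier_chain)) != len(self.classifier_chain):
            raise InvalidInputError("classifier chain entries must be unique")
        for name in self.classifier_chain:
            if name not in CLASSIFIERS:
                raise InvalidInputError(f"unknown classifier {name!r}")
        if self.sorter != "minDeltaE":
            raise InvalidInputError(f"unknown sorter {self.sorter!r}")


@dataclass(frozen=True)
class RankedCandidate:
    candidate: CoMCandidate
    energies: CombinationEnergies
    mfe_cover_pass: bool
    e_pass: bool
    min_delta_e: float
    stratum: int  # number of leading chain classifiers passed (larger = better)
    rank: int  # 1-based final position


def evaluate_combinations(
    seq_a: RnaSequence,
    seq_b: RnaSequence,
    candidate: CoMCandidate,
    predictor,
    ww: Optional[Interaction] = None,
) -> CombinationEnergies:
    """MFE predictions for the four combinations of one candidate.

    ``ww`` may be passed in (it does not depend on the candidate and is
    computed once per sequence pair by the pipeline).
    """
    pos_a, pos_b = candidate.wildtype.pos_a, candidate.wildtype.pos_b
    mut_a = apply_mutation(seq_a, pos_a, candidate.mutant_nt_a)
    mut_b = apply_mutation(seq_b, pos_b, candidate.mutant_nt_b)
    try:
        if ww is None:
            ww = predictor.mfe(seq_a, seq_b)
        wm = predictor.mfe(seq_a, mut_b)
        mw = predictor.mfe(mut_a, seq_b)
        mm = predictor.mfe(mut_a, mut_b)
    except Exception as exc:  # re-raise with candidate identity attached
        raise PredictionError(
            f"prediction failed for candidate {candidate.identity}: {exc}"
        ) from exc
    return CombinationEnergies(ww=ww, wm=wm, mw=mw, mm=mm)


def mfe_cover(candidate: CoMCandidate, energies: CombinationEnergies) -> bool:
    """True iff the mm MFE interaction pairs the two mutated positions."""
    mm = energies.interaction("mm")
    if mm is None:
        return False
    return mm.contains_pair(candidate.wildtype.pos_a, candidate.wildtype.pos_b)


def e_classifier(
    energies: CombinationEnergies, alpha: float, beta: float
) -> tuple[bool, Optional[str]]:
    """Energy-difference constraint; returns (passed, failure reason).

    Absent wm/mw interactions enter as 0 kcal/mol, i.e. maximally
    destabilized mixed combinations.
    """
    if alpha < 0 or beta < 0:
        raise InvalidInputError("alpha and beta must be >= 0")
    ww, mm = energies.mfe_ww, energies.mfe_mm
    if energies.is_none("ww") or ww >= 0:
        return False, "no favorable wildtype-only interaction"
    if energies.is_none("mm") or mm >= 0:
        return False, "no favorable mutant-only interaction"
    mixed = min(energies.mfe_mw, energies.mfe_wm)
    if not ww + alpha < mixed:
        return False, f"MFE(ww)+alpha={ww + alpha:.2f} not < min(mw,wm)={mixed:.2f}"
    if not mm + beta < mixed:
        return False, f"MFE(mm)+beta={mm + beta:.2f} not < min(mw,wm)={mixed:.2f}"
    return True, None


def min_delta_e(energies: CombinationEnergies) -> float:
    """min(MFE(mw), MFE(wm)) - max(MFE(ww), MFE(mm)); none entries count 0."""
    return min(energies.mfe_mw, energies.mfe_wm) - max(
        energies.mfe_ww, energies.mfe_mm
    )


def _stratum(chain: Seq[str], results: dict[str, bool]) -> int:
    n = 0
    for name in chain:
        if not results[name]:
            break
        n += 1
    return n


def rank_candidates(
    evaluated: Seq[tuple[CoMCandidate, CombinationEnergies]],
    config: RankingConfig,
) -> list[RankedCandidate]:
    """Order candidates by stratum, then minDeltaE, with deterministic ties.

    The stratum is the length of the longest prefix of the classifier chain
    whose classifiers all pass (prefix semantics: failing an early
    classifier forfeits credit for later ones).  Ties are broken by
    position in A, then lexicographic mutant pair.
    """
    rows = []
    for cand, energies in evaluated:
        cover = mfe_cover(cand, energies)
        e_pass, _ = e_classifier(energies, config.alpha, config.beta)
        results = {"mfeCover": cover, "E": e_pass}
        mde = min_delta_e(energies)
        rows.append((cand, energies, cover, e_pass, mde,
                     _stratum(config.classifier_chain, results)))
    rows.sort(
        key=lambda r: (
            -r[5],
            -r[4],
            r[0].wildtype.pos_a,
            (r[0].mutant_nt_a, r[0].mutant_nt_b),
        )
    )
    return [
        RankedCandidate(
            candidate=cand,
            energies=energies,
            mfe_cover_pass=cover,
            e_pass=e_pass,
            min_delta_e=mde,
            stratum=stratum,
            rank=i,
        )
        for i, (cand, energies, cover, e_pass, mde, stratum) in enumerate(rows, 1)
    ]


def rank_pair(
    seq_a: RnaSequence,
    seq_b: RnaSequence,
    predictor,
    config: Optional[RankingConfig] = None,
) -> list[RankedCandidate]:
    """Full pipeline: collect, filter, mutate, evaluate and rank.

    Returns an empty list when the wildtype sequences form no favorable
    interaction (there is nothing to verify).
    """
    config = config if config is not None else RankingConfig()
    mfe = predictor.mfe(seq_a, seq_b)
    if mfe is None:
        logger.info("%s vs %s: no favorable wildtype interaction", seq_a.id, seq_b.id)
        return []
    collected = collect_basepairs(
        seq_a,
        seq_b,
        predictor,
        mode=config.collection_mode,
        max_subopt=config.max_subopt,
        mfe=mfe,
    )
    kept = filter_basepairs(collected, config.filters)
    candidates = generate_candidates(kept, mode=config.mutation_mode)
    evaluated = [
        (cand, evaluate_combinations(seq_a, seq_b, cand, predictor, ww=mfe))
        for cand in candidates
    ]
    logger.debug(
        "%s vs %s: %d collected, %d kept, %d candidates",
        seq_a.id, seq_b.id, len(collected), len(kept), len(candidates),
    )
    return rank_candidates(evaluated, config)


# ---------------------------------------------------------------------------
# CSV output
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "rank",
    "pos_a_1based",
    "pos_b_1based",
    "wt_bp",
    "mut_bp",
    "context",
    "mfe_ww",
    "mfe_wm",
    "mfe_mw",
    "mfe_mm",
    "mfeCover",
    "E_pass",
    "minDeltaE",
    "none_ww",
    "none_wm",
    "none_mw",
    "none_mm",
]


def write_results_csv(ranked: Seq[RankedCandidate], destination) -> None:
    """Write the ranked candidate table (RFC 4180, energies to 2 decimals).

    ``destination`` is a path or an open text handle.  Coordinates are
    1-based inclusive; the trailing none_* columns flag combinations with
    no favorable interaction (whose energies are encoded as 0.00).
    """
    own_handle = isinstance(destination, (str, Path))
    handle: IO[str] = (
        open(destination, "w", newline="") if own_handle else destination
    )
    try:
        writer = csv.writer(handle)
        writer.writerow(CSV_COLUMNS)
        for rc in ranked:
            cand = rc.candidate
            writer.writerow(
                [
                    rc.rank,
                    cand.wildtype.pos_a + 1,
                    cand.wildtype.pos_b + 1,
                    cand.wildtype.nt_a + cand.wildtype.nt_b,
                    cand.mutant_nt_a + cand.mutant_nt_b,
                    cand.context.value,
                    f"{rc.energies.mfe_ww:.2f}",
                    f"{rc.energies.mfe_wm:.2f}",
                    f"{rc.energies.mfe_mw:.2f}",
                    f"{rc.energies.mfe_mm:.2f}",
                    rc.mfe_cover_pass,
                    rc.e_pass,
                    f"{rc.min_delta_e:.2f}",
                    rc.energies.is_none("ww"),
                    rc.energies.is_none("wm"),
                    rc.energies.is_none("mw"),
                    rc.energies.is_none("mm"),
                ]
            )
    finally:
        if own_handle:
            handle.close()
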