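"""Compensatory-mutation candidate generation.

Mutable inter-molecular base pairs are collected from the wildtype MFE
interaction (optionally extended with suboptimal interactions inside the
MFE site windows), annotated with their helix context, filtered, and turned
into single-base-pair compensatory mutation (CoM) candidates.

A valid CoM replaces a wildtype pair (a, b) with a pairable mutant pair
(a', b') such that neither mixed combination can pair: a' must not pair
with b and b' must not pair with a, counting the G-U wobble as pairing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence as Seq

from .errors import InvalidInputError
from .interactions import BasePair, Interaction
from .sequence import PAIRABLE, RnaSequence, is_pairable

logger = logging.getLogger(__name__)


class HelixContext(str, Enum):
    """Stacking context of a base pair within its interaction."""

    STACKED_BOTH = "stacked_both"
    HELIX_END = "helix_end"
    LONELY = "lonely"


class MutationMode(str, Enum):
    FLIP = "flip"  # swap the two wildtype nucleotides (GC -> CG)
    ALL = "all"  # every non-compatible pairable alternative


class CollectionMode(str, Enum):
    MFE_ONLY = "mfe_only"
    MFE_PLUS_SUBOPT = "mfe_plus_subopt"


@dataclass(frozen=True)
class CollectedPair:
    """A base pair collected for mutation, with provenance and context."""

    bp: BasePair
    source_rank: int  # 1 = MFE interaction
    context: HelixContext


def _bp_class(nt_a: str, nt_b: str) -> str:
    """Lex-normalized pair class, e.g. both GC and CG -> 'CG'."""
    return "".join(sorted((nt_a, nt_b)))


@dataclass(frozen=True)
class CandidateFilters:
    """User constraints on which collected pairs may be mutated.

    ``allowed_bp_types`` holds lex-normalized pair classes (subset of
    {AU, CG, GU}); entries are normalized on construction, so passing
    "GC" or "UA" works.  Defaults keep all types, drop lonely pairs and
    keep helix ends.
    """

    allowed_bp_types: frozenset[str] = frozenset({"AU", "CG", "GU"})
    exclude_lonely: bool = True
    exclude_helix_ends: bool = False

    def __post_init__(self) -> None:
        normalized = frozenset("".join(sorted(t.upper())) for t in self.allowed_bp_types)
        for t in normalized:
            if t not in {"AU", "CG", "GU"}:
                raise InvalidInputError(f"unknown base-pair type {t!r}")
        if not normalized:
            raise InvalidInputError("allowed_bp_types must be non-empty")
        object.__setattr__(self, "allowed_bp_types", normalized)

    def admits(self, collected: CollectedPair) -> bool:
        if _bp_class(collected.bp.nt_a, collected.bp.nt_b) not in self.allowed_bp_types:
            return False
        if self.exclude_lonely and collected.context is HelixContext.LONELY:
            return False
        if self.exclude_helix_ends and collected.context is HelixContext.HELIX_END:
            return False
        return True


@dataclass(frozen=True)
class CoMCandidate:
    """One wildtype base pair plus its compensatory mutant pair."""

    wildtype: BasePair
    mutant_nt_a: str
    mutant_nt_b: str
    context: HelixContext
    source_rank: int = 1

    def __post_init__(self) -> None:
        wt = self.wildtype
        if not is_pairable(self.mutant_nt_a, self.mutant_nt_b):
            raise InvalidInputError("mutant pair must itself be pairable")
        if (self.mutant_nt_a, self.mutant_nt_b) == (wt.nt_a, wt.nt_b):
            raise InvalidInputError("mutant pair equals the wildtype pair")
        if is_pairable(self.mutant_nt_a, wt.nt_b) or is_pairable(wt.nt_a, self.mutant_nt_b):
            raise InvalidInputError(
                "mutant nucleotides must be non-compatible with their "
                "wildtype counterparts (wobble counts as pairing)"
            )

    @property
    def identity(self) -> tuple[int, int, str, str]:
        return (self.wildtype.pos_a, self.wildtype.pos_b, self.mutant_nt_a, self.mutant_nt_b)


def classify_context(interaction: Interaction, bp: BasePair) -> HelixContext:
    """Stacking context of ``bp`` inside ``interaction``.

    stacked_both if both diagonal neighbors (pos_a-1, pos_b+1) and
    (pos_a+1, pos_b-1) are paired; helix_end if exactly one; lonely if none.
    """
    positions = interaction.pair_positions()
    if (bp.pos_a, bp.pos_b) not in positions:
        raise InvalidInputError(
            f"pair ({bp.pos_a}, {bp.pos_b}) is not part of the interaction"
        )
    left = (bp.pos_a - 1, bp.pos_b + 1) in positions
    right = (bp.pos_a + 1, bp.pos_b - 1) in positions
    if left and right:
        return HelixContext.STACKED_BOTH
    if left or right:
        return HelixContext.HELIX_END
    return HelixContext.LONELY


def collect_basepairs(
    seq_a: RnaSequence,
    seq_b: RnaSequence,
    predictor,
    mode: CollectionMode = CollectionMode.MFE_ONLY,
    max_subopt: int = 20,
    mfe: Optional[Interaction] = None,
) -> list[CollectedPair]:
    """Base pairs considered for mutation, with source rank and context.

    ``mfe_only`` returns exactly the MFE interaction's pairs (rank 1).
    ``mfe_plus_subopt`` additionally enumerates suboptimal interactions
    restricted to the MFE's site windows and unions their pairs,
    de-duplicated by position with the best (lowest) source rank kept; the
    helix context of a duplicated pair is taken from the best-ranked
    interaction containing it (MFE context wins).
    """
    if mfe is None:
        mfe = predictor.mfe(seq_a, seq_b)
    if mfe is None:
        return []
    collected: dict[tuple[int, int], CollectedPair] = {}
    for bp in mfe.pairs:
        collected[(bp.pos_a, bp.pos_b)] = CollectedPair(
            bp=bp, source_rank=1, context=classify_context(mfe, bp)
        )
    if mode is CollectionMode.MFE_PLUS_SUBOPT:
        region = ((mfe.start_a, mfe.end_a), (mfe.start_b, mfe.end_b))
        subopts = predictor.suboptimals(seq_a, seq_b, max_count=max_subopt, region=region)
        for rank, inter in enumerate(subopts, start=1):
            for bp in inter.pairs:
                key = (bp.pos_a, bp.pos_b)
                if key not in collected:
                    collected[key] = CollectedPair(
                        bp=bp, source_rank=rank, context=classify_context(inter, bp)
                    )
    out = sorted(collected.values(), key=lambda c: (c.bp.pos_a, c.bp.pos_b))
    logger.debug("collected %d base pairs (%s)", len(out), mode.value)
    return out


def filter_basepairs(
    collected: Seq[CollectedPair], filters: CandidateFilters
) -> list[CollectedPair]:
    """Subset of ``collected`` admitted by the filters; order preserved."""
    return [c for c in collected if filters.admits(c)]


def mutation_alternatives(
    nt_a: str, nt_b: str, mode: MutationMode = MutationMode.FLIP
) -> list[tuple[str, str]]:
    """Compensatory mutant pairs for a wildtype pair, sorted lexicographically.

    flip: the single nucleotide swap (nt_b, nt_a).  all: every pairable
    (x, y) with x not pairable with the wildtype nt_b, y not pairable with
    the wildtype nt_a, and (x, y) != (nt_a, nt_b); the wobble counts as
    pairing in the exclusion checks, so each wildtype type has exactly
    three alternatives.
    """
    if not is_pairable(nt_a, nt_b):
        raise InvalidInputError(f"{nt_a}-{nt_b} is not a pairable wildtype pair")
    if mode is MutationMode.FLIP:
        return [(nt_b, nt_a)]
    alts = [
        (x, y)
        for (x, y) in sorted(PAIRABLE)
        if (x, y) != (nt_a, nt_b)
        and not is_pairable(x, nt_b)
        and not is_pairable(nt_a, y)
    ]
    return alts


def generate_candidates(
    collected: Seq[CollectedPair],
    mode: MutationMode = MutationMode.FLIP,
) -> list[CoMCandidate]:
    """Expand collected pairs into CoM candidates, merged on identity.

    Candidate identity is (pos_a, pos_b, mutant pair); duplicates keep the
    lowest source rank.
    """
    merged: dict[tuple[int, int, str, str], CoMCandidate] = {}
    for cp in collected:
        for (x, y) in mutation_alternatives(cp.bp.nt_a, cp.bp.nt_b, mode):
            cand = CoMCandidate(
                wildtype=cp.bp,
                mutant_nt_a=x,
                mutant_nt_b=y,
                context=cp.context,
                source_rank=cp.source_rank,
            )
            prev = merged.get(cand.identity)
            if prev is None or cand.source_rank < prev.source_rank:
                merged[cand.identity] = cand
    return sorted(merged.values(), key=lambda c: c.identity)
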