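"""Minimum-free-energy RNA-RNA duplex prediction.

The model considers a single inter-molecular interaction site: a strictly
antiparallel chain of base pairs (``pos_a`` increasing, ``pos_b``
decreasing) with at most ``max_loop_side`` unpaired residues between
consecutive pairs on either sequence and no intra-molecular structure
inside the site.  The total energy is

    e_total = init + sum(stack or loop terms) + ED_A(site_A) + ED_B(site_B)

and only favorable interactions (e_total < 0) are reported.

``duplex_mfe``/``enumerate_suboptimals`` run an exact dynamic program
anchored at every possible 5'-most pair, which yields the optimal chain for
*every* boundary quadruple (start_a, end_a, start_b, end_b).  This keeps the
accessibility term exact for arbitrary providers (it only depends on the
boundaries) and directly provides the one-interaction-per-boundary
suboptimal list.  The cost is roughly O(P^2 * w) for P pairable position
pairs and loop window w, which targets site-scale inputs (tens of
nucleotides per sequence), not transcriptome scans.

``brute_force_duplex_mfe`` is an independent oracle: it exhaustively
enumerates every valid chain on small inputs.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

from .accessibility import AccessibilityProvider, ZeroAccessibility
from .errors import InvalidInputError, OracleSizeError
from .interactions import BasePair, Interaction
from .params import EnergyParameters, default_parameters
from .sequence import PAIRABLE as _PAIRABLE_SET
from .sequence import RnaSequence, is_pairable

logger = logging.getLogger(__name__)

#: Optional search restriction: 0-based inclusive windows on A and B.
Region = tuple[tuple[int, int], tuple[int, int]]

_ROUND = 9  # energy rounding for deterministic tie-breaking


def _cells(a: RnaSequence, b: RnaSequence, region: Optional[Region]) -> list[tuple[int, int]]:
    """All pairable (pos_a, pos_b) cells, sorted by pos_a asc, pos_b desc."""
    if region is None:
        ra = range(len(a))
        rb = range(len(b))
    else:
        (a_lo, a_hi), (b_lo, b_hi) = region
        if not (0 <= a_lo <= a_hi < len(a) and 0 <= b_lo <= b_hi < len(b)):
            raise InvalidInputError(f"region {region} out of sequence bounds")
        ra = range(a_lo, a_hi + 1)
        rb = range(b_lo, b_hi + 1)
    out = [
        (i, j)
        for i in ra
        for j in rb
        if (a.residues[i], b.residues[j]) in _PAIRABLE_SET
    ]
    out.sort(key=lambda c: (c[0], -c[1]))
    return out


def _step_energy(
    a: str, b: str, k: int, l: int, i: int, j: int, params: EnergyParameters
) -> float:
    """Energy of extending a chain from pair (k,l) to the next pair (i,j)."""
    gap_a = i - k - 1
    gap_b = l - j - 1
    if gap_a == 0 and gap_b == 0:
        return params.stack_table[(a[k], b[l], a[i], b[j])]
    return params.loop_penalty.cost(gap_a, gap_b)


def _boundary_optima(
    a: RnaSequence,
    b: RnaSequence,
    params: EnergyParameters,
    region: Optional[Region],
) -> dict[tuple[int, int, int, int], tuple[float, tuple[tuple[int, int], ...]]]:
    """Best hybridization energy (and chain) per boundary quadruple.

    Every chain with leftmost pair (s,t) and rightmost pair (i,j) has
    boundary (s, i, j, t); the anchored DP below minimizes over all chains
    sharing that boundary.
    """
    cells = _cells(a, b, region)
    if not cells:
        return {}
    res_a, res_b = a.residues, b.residues
    window = params.max_loop_side + 1  # max index step between paired positions

    # Predecessor lists and step energies, shared across all start anchors.
    cell_set = set(cells)
    preds: dict[tuple[int, int], list[tuple[tuple[int, int], float]]] = {}
    for (i, j) in cells:
        plist = []
        for k in range(max(0, i - window), i):
            for l in range(j + 1, j + window + 1):
                if (k, l) in cell_set:
                    plist.append(
                        ((k, l), _step_energy(res_a, res_b, k, l, i, j, params))
                    )
        preds[(i, j)] = plist

    optima: dict[tuple[int, int, int, int], tuple[float, tuple[tuple[int, int], ...]]] = {}
    for idx, (s, t) in enumerate(cells):
        F: dict[tuple[int, int], float] = {(s, t): params.init_penalty}
        parent: dict[tuple[int, int], tuple[int, int]] = {}
        # cells are sorted by pos_a asc, so predecessors are always final
        for (i, j) in cells[idx + 1 :]:
            if i <= s or j >= t:
                continue
            best = None
            best_p = None
            for (p, step) in preds[(i, j)]:
                e_prev = F.get(p)
                if e_prev is None:
                    continue
                e = e_prev + step
                if best is None or e < best:
                    best, best_p = e, p
            if best is not None:
                F[(i, j)] = best
                parent[(i, j)] = best_p
        for (i, j), e_hyb in F.items():
            chain = [(i, j)]
            while chain[-1] in parent:
                chain.append(parent[chain[-1]])
            chain.reverse()
            optima[(s, i, j, t)] = (e_hyb, tuple(chain))
    return optima


def _build_interaction(
    a: RnaSequence,
    b: RnaSequence,
    chain: Iterable[tuple[int, int]],
    e_hybrid: float,
    acc: AccessibilityProvider,
) -> Interaction:
    pairs = tuple(
        BasePair(pos_a=i, pos_b=j, nt_a=a.residues[i], nt_b=b.residues[j])
        for (i, j) in chain
    )
    ed_a = acc.ed(a, pairs[0].pos_a, pairs[-1].pos_a)
    ed_b = acc.ed(b, pairs[-1].pos_b, pairs[0].pos_b)
    return Interaction(
        pairs=pairs,
        e_hybrid=e_hybrid,
        ed_a=ed_a,
        ed_b=ed_b,
        e_total=e_hybrid + ed_a + ed_b,
    )


def enumerate_suboptimals(
    seq_a: RnaSequence,
    seq_b: RnaSequence,
    params: Optional[EnergyParameters] = None,
    acc: Optional[AccessibilityProvider] = None,
    max_count: int = 100,
    region: Optional[Region] = None,
) -> list[Interaction]:
    """Energy-sorted favorable interactions, one per boundary quadruple.

    Returns at most ``max_count`` interactions with ``e_total < 0``, sorted
    by ascending ``e_total``; equal energies are broken by the
    lexicographically smallest boundary (start_a, end_a, start_b, end_b).
    The head of the list is the (region-restricted) MFE interaction.
    """
    if max_count < 1:
        raise InvalidInputError("max_count must be >= 1")
    params = params if params is not None else default_parameters()
    acc = acc if acc is not None else ZeroAccessibility()

    scored: list[tuple[float, tuple[int, int, int, int], Interaction]] = []
    for boundary, (e_hyb, chain) in _boundary_optima(seq_a, seq_b, params, region).items():
        inter = _build_interaction(seq_a, seq_b, chain, e_hyb, acc)
        if inter.e_total < 0.0:
            scored.append((round(inter.e_total, _ROUND), boundary, inter))
    scored.sort(key=lambda item: (item[0], item[1]))
    logger.debug(
        "%s vs %s: %d favorable boundaries (returning <= %d)",
        seq_a.id, seq_b.id, len(scored), max_count,
    )
    return [inter for _, _, inter in scored[:max_count]]


def duplex_mfe(
    seq_a: RnaSequence,
    seq_b: RnaSequence,
    params: Optional[EnergyParameters] = None,
    acc: Optional[AccessibilityProvider] = None,
    region: Optional[Region] = None,
) -> Optional[Interaction]:
    """The most stable favorable interaction, or None if none has e_total < 0."""
    best = enumerate_suboptimals(
        seq_a, seq_b, params=params, acc=acc, max_count=1, region=region
    )
    return best[0] if best else None


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

#: Size guard for exhaustive enumeration.
ORACLE_MAX_LEN = 12


def _brute_force_enumerate(
    seq_a: RnaSequence,
    seq_b: RnaSequence,
    params: Optional[EnergyParameters] = None,
    acc: Optional[AccessibilityProvider] = None,
) -> dict[tuple[int, int, int, int], tuple[float, float, tuple]]:
    """Recursively enumerate every valid chain; keep the best per boundary.

    Independent of the DP path: chains are enumerated recursively and their
    energies summed term by term.  Guarded to sequences of at most
    ``ORACLE_MAX_LEN`` nt each.
    """
    if len(seq_a) > ORACLE_MAX_LEN or len(seq_b) > ORACLE_MAX_LEN:
        raise OracleSizeError(
            f"brute force refused: sequences longer than {ORACLE_MAX_LEN} nt"
        )
    params = params if params is not None else default_parameters()
    acc = acc if acc is not None else ZeroAccessibility()
    res_a, res_b = seq_a.residues, seq_b.residues
    max_loop = params.max_loop_side

    cells = [
        (i, j)
        for i in range(len(res_a))
        for j in range(len(res_b))
        if is_pairable(res_a[i], res_b[j])
    ]
    # per boundary: (e_total, e_hybrid, chain of (pos_a, pos_b))
    best: dict[tuple[int, int, int, int], tuple[float, float, tuple]] = {}

    def record(chain: tuple, e_hyb: float) -> None:
        s, t = chain[0]
        i, j = chain[-1]
        e_total = e_hyb + acc.ed(seq_a, s, i) + acc.ed(seq_b, j, t)
        key = (s, i, j, t)
        if key not in best or e_total < best[key][0]:
            best[key] = (e_total, e_hyb, chain)

    def extend(chain: tuple, e_hyb: float) -> None:
        record(chain, e_hyb)
        i, j = chain[-1]
        for (k, l) in cells:
            if not (i < k <= i + 1 + max_loop and j - 1 - max_loop <= l < j):
                continue
            gap_a = k - i - 1
            gap_b = j - l - 1
            if gap_a == 0 and gap_b == 0:
                step = params.stack_table[(res_a[i], res_b[j], res_a[k], res_b[l])]
            else:
                step = params.loop_penalty.cost(gap_a, gap_b)
            extend(chain + ((k, l),), e_hyb + step)

    for cell in cells:
        extend((cell,), params.init_penalty)
    return best


def brute_force_boundary_optima(
    seq_a: RnaSequence,
    seq_b: RnaSequence,
    params: Optional[EnergyParameters] = None,
    acc: Optional[AccessibilityProvider] = None,
) -> dict[tuple[int, int, int, int], float]:
    """Exhaustive per-boundary minimum of e_total over all valid chains."""
    return {
        bnd: e_total
        for bnd, (e_total, _, _) in _brute_force_enumerate(
            seq_a, seq_b, params=params, acc=acc
        ).items()
    }


def brute_force_duplex_mfe(
    seq_a: RnaSequence,
    seq_b: RnaSequence,
    params: Optional[EnergyParameters] = None,
    acc: Optional[AccessibilityProvider] = None,
) -> Optional[Interaction]:
    """Oracle MFE with the same contract as :func:`duplex_mfe` (favorability,
    lexicographic boundary tie-break), computed by exhaustive enumeration."""
    acc = acc if acc is not None else ZeroAccessibility()
    best = _brute_force_enumerate(seq_a, seq_b, params=params, acc=acc)
    favorable = sorted(
        (round(e_total, _ROUND), bnd, e_hyb, chain)
        for bnd, (e_total, e_hyb, chain) in best.items()
        if e_total < 0.0
    )
    if not favorable:
        return None
    _, _, e_hyb, chain = favorable[0]
    return _build_interaction(seq_a, seq_b, chain, e_hyb, acc)


# ---------------------------------------------------------------------------
# Predictor interface
# ---------------------------------------------------------------------------


class BuiltinPredictor:
    """The package's own duplex model behind the generic predictor interface.

    A predictor exposes ``mfe(a, b, region=None)`` and
    ``suboptimals(a, b, max_count, region=None)``.  Results are memoized per
    (residues, region) because candidate evaluation re-queries identical
    sequence combinations.
    """

    def __init__(
        self,
        params: Optional[EnergyParameters] = None,
        accessibility: Optional[AccessibilityProvider] = None,
    ) -> None:
        self.params = params if params is not None else default_parameters()
        self.accessibility = (
            accessibility if accessibility is not None else ZeroAccessibility()
        )
        self._cache: dict = {}

    def _key(self, a: RnaSequence, b: RnaSequence, extra) -> tuple:
        # keyed on id+residues: window-table accessibility is id-addressed
        return (a.id, a.residues, b.id, b.residues, extra)

    def mfe(
        self, a: RnaSequence, b: RnaSequence, region: Optional[Region] = None
    ) -> Optional[Interaction]:
        key = self._key(a, b, ("mfe", region))
        if key not in self._cache:
            self._cache[key] = duplex_mfe(
                a, b, params=self.params, acc=self.accessibility, region=region
            )
        return self._cache[key]

    def suboptimals(
        self,
        a: RnaSequence,
        b: RnaSequence,
        max_count: int,
        region: Optional[Region] = None,
    ) -> list[Interaction]:
        key = self._key(a, b, ("sub", max_count, region))
        if key not in self._cache:
            self._cache[key] = enumerate_suboptimals(
                a,
                b,
                params=self.params,
                acc=self.accessibility,
                max_count=max_count,
                region=region,
            )
        return self._cache[key]
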