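"""Nearest-neighbor energy parameters for inter-molecular RNA duplexes.

The stacking free energies are the published Turner 2004 RNA/RNA
nearest-neighbor increments at 37 degC (kcal/mol), as distributed with
ViennaRNA's ``rna_turner2004.par`` (``stack`` block).  Interior loops and
bulges between consecutive inter-molecular pairs are charged with a simple
affine penalty instead of the full tabulated loop model: this package's
energies are a stability *proxy* for comparing mutation candidates, not a
replacement for a full interaction predictor, and every energy-dependent
test is verified against a brute-force oracle sharing the same table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .errors import InvalidInputError
from .sequence import PAIRABLE

# Ordered pair types, matching the row/column order of the published matrix.
_PAIR_ORDER = [("C", "G"), ("G", "C"), ("G", "U"), ("U", "G"), ("A", "U"), ("U", "A")]

# Turner 2004 stacking free energies, kcal/mol at 37 degC.  Entry [p][q] is
# the increment for pair p = (X1,Y1) stacked 5'-side of the duplex
# continuation whose pair read bottom-to-top is q = (Y2,X2):
#   5'-X1 X2-3'
#   3'-Y1 Y2-5'   ->  _STACK_MATRIX[index(X1,Y1)][index(Y2,X2)]
# The matrix is symmetric, which encodes the reverse-complement symmetry of
# the nearest-neighbor model.
_STACK_MATRIX = [
    #  CG     GC     GU     UG     AU     UA
    [-2.40, -3.30, -2.10, -1.40, -2.10, -2.10],  # CG
    [-3.30, -3.40, -2.50, -1.50, -2.20, -2.40],  # GC
    [-2.10, -2.50, +1.30, -0.50, -1.40, -1.30],  # GU
    [-1.40, -1.50, -0.50, +0.30, -0.60, -1.00],  # UG
    [-2.10, -2.20, -1.40, -0.60, -1.10, -0.90],  # AU
    [-2.10, -2.40, -1.30, -1.00, -0.90, -1.30],  # UA
]

_PAIR_INDEX = {p: i for i, p in enumerate(_PAIR_ORDER)}


def _build_stack_table() -> dict[tuple[str, str, str, str], float]:
    """Re-key the matrix as (X1, Y1, X2, Y2) -> kcal/mol."""
    table: dict[tuple[str, str, str, str], float] = {}
    for (x1, y1), i in _PAIR_INDEX.items():
        for (x2, y2) in _PAIR_ORDER:
            j = _PAIR_INDEX[(y2, x2)]
            table[(x1, y1, x2, y2)] = _STACK_MATRIX[i][j]
    return table


#: Stacking increments keyed by (nt_a_5', nt_b_3', nt_a_next, nt_b_next).
TURNER2004_STACKS: Mapping[tuple[str, str, str, str], float] = _build_stack_table()

#: Duplex initiation free energy, kcal/mol (Turner 2004).
DUPLEX_INIT = 4.10


@dataclass(frozen=True)
class LoopPenalty:
    """Affine penalty for an interior loop / bulge between consecutive pairs.

    ``cost(ga, gb) = base + per_unpaired * (ga + gb) + per_asymmetry * |ga - gb|``
    where ``ga``/``gb`` are the unpaired residue counts on the two sequences.
    ``per_unpaired >= per_asymmetry`` is enforced so the penalty is monotone
    non-decreasing in loop size.  Defaults are a coarse fit to the magnitude
    of tabulated Turner interior-loop costs.
    """

    base: float = 1.0
    per_unpaired: float = 0.5
    per_asymmetry: float = 0.3

    def __post_init__(self) -> None:
        if min(self.base, self.per_unpaired, self.per_asymmetry) < 0:
            raise InvalidInputError("loop penalty coefficients must be >= 0")
        if self.per_unpaired < self.per_asymmetry:
            raise InvalidInputError(
                "per_unpaired must be >= per_asymmetry for a monotone penalty"
            )

    def cost(self, gap_a: int, gap_b: int) -> float:
        if gap_a < 0 or gap_b < 0 or gap_a + gap_b == 0:
            raise InvalidInputError(
                f"invalid loop gaps ({gap_a}, {gap_b}): need >= 1 unpaired"
            )
        return (
            self.base
            + self.per_unpaired * (gap_a + gap_b)
            + self.per_asymmetry * abs(gap_a - gap_b)
        )


@dataclass(frozen=True)
class EnergyParameters:
    """Complete parameter set of the duplex energy model.

    stack_table
        Increment for each ordered pair of stacked pairable base pairs,
        keyed ``(nt_a, nt_b, next_nt_a, next_nt_b)``; kcal/mol.
    loop_penalty
        Affine interior-loop/bulge cost (see :class:`LoopPenalty`).
    init_penalty
        Duplex initiation constant, kcal/mol.
    max_loop_side
        Maximum unpaired stretch allowed between consecutive pairs on either
        sequence.
    """

    stack_table: Mapping[tuple[str, str, str, str], float] = field(
        default_factory=lambda: TURNER2004_STACKS
    )
    loop_penalty: LoopPenalty = field(default_factory=LoopPenalty)
    init_penalty: float = DUPLEX_INIT
    max_loop_side: int = 16

    def __post_init__(self) -> None:
        if self.max_loop_side < 0:
            raise InvalidInputError("max_loop_side must be >= 0")
        for p in PAIRABLE:
            for q in PAIRABLE:
                key = (*p, *q)
                if key not in self.stack_table:
                    raise InvalidInputError(f"stack_table misses entry {key}")

    def stack(self, nt_a: str, nt_b: str, next_nt_a: str, next_nt_b: str) -> float:
        return self.stack_table[(nt_a, nt_b, next_nt_a, next_nt_b)]


def default_parameters() -> EnergyParameters:
    """The package default: Turner 2004 stacks, affine loops, init +4.10."""
    return EnergyParameters()
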