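"""Inter-molecular interaction records.

An interaction is an ordered, strictly antiparallel set of inter-molecular
base pairs together with its energy decomposition: hybridization energy
plus the two accessibility penalties.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidInputError
from .sequence import is_pairable

_E_TOL = 1e-6


@dataclass(frozen=True, order=True)
class BasePair:
    """One inter-molecular pair: position ``pos_a`` of A with ``pos_b`` of B.

    Positions are 0-based; ``nt_a``/``nt_b`` are the paired residues.
    """

    pos_a: int
    pos_b: int
    nt_a: str
    nt_b: str

    def __post_init__(self) -> None:
        if self.pos_a < 0 or self.pos_b < 0:
            raise InvalidInputError("base-pair positions must be >= 0")
        if not is_pairable(self.nt_a, self.nt_b):
            raise InvalidInputError(
                f"{self.nt_a}-{self.nt_b} at ({self.pos_a}, {self.pos_b}) "
                "is not a pairable combination"
            )

    @property
    def bp_type(self) -> str:
        return self.nt_a + self.nt_b


@dataclass(frozen=True)
class Interaction:
    """A predicted RNA-RNA interaction.

    ``pairs`` are sorted by ``pos_a`` ascending; antiparallelity means
    ``pos_b`` is then strictly decreasing.  ``e_total`` must equal
    ``e_hybrid + ed_a + ed_b`` (floating tolerance); energies in kcal/mol.
    """

    pairs: tuple[BasePair, ...]
    e_hybrid: float
    ed_a: float
    ed_b: float
    e_total: float

    def __post_init__(self) -> None:
        if not self.pairs:
            raise InvalidInputError("interaction needs at least one base pair")
        for prev, nxt in zip(self.pairs, self.pairs[1:]):
            if not (nxt.pos_a > prev.pos_a and nxt.pos_b < prev.pos_b):
                raise InvalidInputError(
                    "pairs must be strictly antiparallel "
                    "(pos_a increasing, pos_b decreasing)"
                )
        if self.ed_a < 0 or self.ed_b < 0:
            raise InvalidInputError("ED penalties must be >= 0")
        if abs(self.e_total - (self.e_hybrid + self.ed_a + self.ed_b)) > _E_TOL:
            raise InvalidInputError(
                "e_total must decompose as e_hybrid + ed_a + ed_b"
            )

    # -- boundaries (0-based inclusive) ------------------------------------
    @property
    def start_a(self) -> int:
        return self.pairs[0].pos_a

    @property
    def end_a(self) -> int:
        return self.pairs[-1].pos_a

    @property
    def start_b(self) -> int:
        return self.pairs[-1].pos_b

    @property
    def end_b(self) -> int:
        return self.pairs[0].pos_b

    @property
    def boundary(self) -> tuple[int, int, int, int]:
        """(start_a, end_a, start_b, end_b), the interaction's site windows."""
        return (self.start_a, self.end_a, self.start_b, self.end_b)

    def contains_pair(self, pos_a: int, pos_b: int) -> bool:
        return any(bp.pos_a == pos_a and bp.pos_b == pos_b for bp in self.pairs)

    def pair_positions(self) -> set[tuple[int, int]]:
        return {(bp.pos_a, bp.pos_b) for bp in self.pairs}
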