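"""RNA sequences and base-pairing rules.

Sequences are plain 5'->3' residue strings over {A,C,G,U}; DNA input is
folded to RNA (T->U) and upper-cased on construction.  Pairing follows the
canonical Watson-Crick pairs plus the G-U wobble, which counts as pairable
both for duplex formation and for mutant/wildtype incompatibility checks.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidInputError, InvalidSequenceError

RNA_ALPHABET = frozenset("ACGU")

#: Ordered pairable nucleotide pairs: Watson-Crick plus the G-U wobble.
PAIRABLE: frozenset[tuple[str, str]] = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)

_WC_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def is_pairable(nt_a: str, nt_b: str) -> bool:
    """True iff ``nt_a``-``nt_b`` can form a canonical or wobble base pair.

    Raises :class:`InvalidSequenceError` for residues outside {A,C,G,U}.
    """
    for nt in (nt_a, nt_b):
        if nt not in RNA_ALPHABET:
            raise InvalidSequenceError(f"not an RNA residue: {nt!r}")
    return (nt_a, nt_b) in PAIRABLE


def normalize_residues(raw: str) -> str:
    """Upper-case and fold T->U; reject anything outside {A,C,G,U,T}."""
    residues = raw.upper().replace("T", "U")
    for i, nt in enumerate(residues):
        if nt not in RNA_ALPHABET:
            raise InvalidSequenceError(
                f"illegal residue {raw[i]!r} at position {i + 1}"
            )
    return residues


@dataclass(frozen=True)
class RnaSequence:
    """A labelled RNA sequence (residues 5'->3').

    Use :meth:`from_raw` to build from arbitrary user text (applies T->U
    normalization and case folding); the constructor itself requires
    already-normalized residues.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise InvalidSequenceError(f"sequence {self.id!r} is empty")
        for i, nt in enumerate(self.residues):
            if nt not in RNA_ALPHABET:
                raise InvalidSequenceError(
                    f"sequence {self.id!r}: illegal residue {nt!r} "
                    f"at position {i + 1}"
                )

    @classmethod
    def from_raw(cls, id: str, raw: str) -> "RnaSequence":
        return cls(id=id, residues=normalize_residues(raw))

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, pos: int) -> str:
        return self.residues[pos]


def apply_mutation(seq: RnaSequence, pos: int, nt: str) -> RnaSequence:
    """Return a copy of ``seq`` with residue ``pos`` (0-based) set to ``nt``.

    The derived id encodes the mutation 1-based (``<id>|m<pos><nt>``) so
    mutant sequences remain addressable, e.g. by the external-prediction
    adapter.  The input sequence is never modified.
    """
    if nt not in RNA_ALPHABET:
        raise InvalidSequenceError(f"not an RNA residue: {nt!r}")
    if not 0 <= pos < len(seq):
        raise InvalidInputError(
            f"position {pos} out of range for sequence {seq.id!r} "
            f"(length {len(seq)})"
        )
    residues = seq.residues[:pos] + nt + seq.residues[pos + 1 :]
    return RnaSequence(id=f"{seq.id}|m{pos + 1}{nt}", residues=residues)


def reverse_complement(residues: str) -> str:
    """Watson-Crick reverse complement of an RNA residue string."""
    return "".join(_WC_COMPLEMENT[nt] for nt in reversed(residues))
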