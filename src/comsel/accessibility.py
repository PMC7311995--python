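"""Accessibility (ED) penalty providers.

The ED term approximates the free energy needed to open the intra-molecular
structure over the subsequence covered by an interaction; it is added to the
hybridization energy.  Exact partition-function EDs are intentionally out of
scope: users needing predictor-grade energies can feed precomputed
interactions through the external adapter instead.

A provider maps ``(sequence, start, end)`` (0-based inclusive window) to a
penalty >= 0 in kcal/mol; the empty window costs 0.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Protocol, runtime_checkable

from .errors import InvalidInputError
from .sequence import RnaSequence


@runtime_checkable
class AccessibilityProvider(Protocol):
    def ed(self, seq: RnaSequence, start: int, end: int) -> float:
        """ED penalty (kcal/mol, >= 0) for opening seq[start..end]."""
        ...


class ZeroAccessibility:
    """Fully accessible sequences: every window costs 0 (the default)."""

    def ed(self, seq: RnaSequence, start: int, end: int) -> float:
        return 0.0


@dataclass(frozen=True)
class ConstantAccessibility:
    """A flat per-nucleotide opening cost (kcal/mol/nt)."""

    per_nucleotide: float

    def __post_init__(self) -> None:
        if self.per_nucleotide < 0:
            raise InvalidInputError("per-nucleotide ED must be >= 0")

    def ed(self, seq: RnaSequence, start: int, end: int) -> float:
        if end < start:
            return 0.0
        return self.per_nucleotide * (end - start + 1)


@dataclass(frozen=True)
class WindowTableAccessibility:
    """EDs from a user-supplied window table.

    ``table`` maps ``(sequence id, start, end)`` (0-based inclusive) to an
    ED value.  Windows absent from the table cost 0 — the table is an
    override, not a requirement, so partially annotated inputs stay usable.
    """

    table: Mapping[tuple[str, int, int], float]

    def __post_init__(self) -> None:
        for key, value in self.table.items():
            if value < 0:
                raise InvalidInputError(f"negative ED for window {key}")

    def ed(self, seq: RnaSequence, start: int, end: int) -> float:
        if end < start:
            return 0.0
        return float(self.table.get((seq.id, start, end), 0.0))


def load_accessibility_table(path: str | Path) -> WindowTableAccessibility:
    """Read a TSV of per-window EDs.

    Columns: sequence id, window start, window end (1-based inclusive),
    ED value in kcal/mol.  A header line starting with ``id`` is skipped.
    """
    table: dict[tuple[str, int, int], float] = {}
    with open(path, newline="") as handle:
        for ln, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if ln == 1 and row[0].lower() in {"id", "seq_id", "sequence"}:
                continue
            if len(row) != 4:
                raise InvalidInputError(
                    f"{path}: line {ln}: expected 4 tab-separated fields"
                )
            seq_id, start_s, end_s, ed_s = row
            try:
                start, end, ed = int(start_s), int(end_s), float(ed_s)
            except ValueError as exc:
                raise InvalidInputError(f"{path}: line {ln}: {exc}") from exc
            if start < 1 or end < start:
                raise InvalidInputError(
                    f"{path}: line {ln}: bad window [{start}, {end}]"
                )
            table[(seq_id, start - 1, end - 1)] = ed
    return WindowTableAccessibility(table=table)
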