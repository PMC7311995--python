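"""FASTA parsing and the external-prediction adapter.

The adapter lets users substitute any interaction predictor for the
built-in duplex model: interactions are precomputed externally, written to
a CSV keyed by sequence ids, and served through the same predictor
interface the ranking pipeline uses.  Mutant sequences produced by
:func:`comsel.sequence.apply_mutation` carry deterministic derived ids
(``<id>|m<pos1based><nt>``), so all four combinations of a candidate are
addressable.
"""

from __future__ import annotations

import io
import re
from collections import defaultdict
from pathlib import Path
from typing import Optional

import pandas as pd
from Bio import SeqIO

from .errors import InvalidInputError, PredictionError
from .interactions import BasePair, Interaction
from .sequence import RnaSequence

_E_TOL = 1e-4  # tolerance for the e_total decomposition check on input


def parse_fasta(source: str | Path) -> list[RnaSequence]:
    """Parse FASTA from a path or raw text into normalized RNA sequences.

    Ids are taken from the header up to the first whitespace; residues are
    upper-cased with T->U folding.  Illegal residues are reported with
    their 1-based position.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith(">")
    ):
        handle = open(source)
    else:
        handle = io.StringIO(source)
    with handle:
        records = list(SeqIO.parse(handle, "fasta"))
    if not records:
        raise InvalidInputError("no FASTA records found")
    out = []
    for rec in records:
        try:
            out.append(RnaSequence.from_raw(rec.id, str(rec.seq)))
        except ValueError as exc:
            raise InvalidInputError(f"record {rec.id!r}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# External interaction records
# ---------------------------------------------------------------------------

EXTERNAL_COLUMNS = [
    "id_a",
    "id_b",
    "start_a",
    "end_a",
    "start_b",
    "end_b",
    "e_total",
    "e_hybrid",
    "ed_a",
    "ed_b",
    "bp_list",
]

_BP_TOKEN = re.compile(r"\((\d+),(\d+)\)")


def _parse_bp_list(text: str) -> list[tuple[int, int]]:
    tokens = _BP_TOKEN.findall(text)
    if not tokens or _BP_TOKEN.sub("", text).strip("; ,"):
        raise InvalidInputError(f"malformed bp_list {text!r}")
    return [(int(i), int(j)) for i, j in tokens]


def parse_external_interactions(
    path: str | Path,
) -> list[tuple[str, str, Interaction]]:
    """Read precomputed interactions: (id_a, id_b, interaction) triples.

    Coordinates in the file are 1-based inclusive and converted to 0-based
    internally; base pairs must be antiparallel, consistent with the stated
    boundaries, and the energy decomposition e_total = e_hybrid + ed_a +
    ed_b must hold.  Nucleotide identities are not stored in the file, so
    pairs are validated against the boundaries only and materialized when a
    sequence is available (see :class:`ExternalPredictor`).
    """
    df = pd.read_csv(path)
    missing = set(EXTERNAL_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
    out: list[tuple[str, str, Interaction]] = []
    for ln, row in enumerate(df.itertuples(), start=2):
        try:
            boundary = tuple(
                int(getattr(row, c)) for c in ("start_a", "end_a", "start_b", "end_b")
            )
            energies = tuple(
                float(getattr(row, c)) for c in ("e_total", "e_hybrid", "ed_a", "ed_b")
            )
        except (TypeError, ValueError) as exc:
            raise InvalidInputError(f"{path}: line {ln}: {exc}") from exc
        start_a, end_a, start_b, end_b = boundary
        e_total, e_hybrid, ed_a, ed_b = energies
        if abs(e_total - (e_hybrid + ed_a + ed_b)) > _E_TOL:
            raise InvalidInputError(
                f"{path}: line {ln}: e_total does not decompose"
            )
        bps = _parse_bp_list(str(row.bp_list))
        pos = [(i - 1, j - 1) for i, j in bps]
        for (i, j) in pos:
            if not (start_a - 1 <= i <= end_a - 1 and start_b - 1 <= j <= end_b - 1):
                raise InvalidInputError(
                    f"{path}: line {ln}: base pair ({i + 1},{j + 1}) outside "
                    f"boundaries"
                )
        pos.sort()
        first, last = pos[0], pos[-1]
        if (first[0], last[0], last[1], first[1]) != (
            start_a - 1,
            end_a - 1,
            start_b - 1,
            end_b - 1,
        ):
            raise InvalidInputError(
                f"{path}: line {ln}: bp_list inconsistent with boundaries"
            )
        for (pi, pj), (ni, nj) in zip(pos, pos[1:]):
            if not (ni > pi and nj < pj):
                raise InvalidInputError(
                    f"{path}: line {ln}: bp_list is not antiparallel"
                )
        # store positions; nucleotides are bound lazily by the predictor
        out.append(
            (
                str(row.id_a),
                str(row.id_b),
                _LazyInteraction(pos, e_hybrid, ed_a, ed_b, e_total),  # type: ignore[arg-type]
            )
        )
    return out


class _LazyInteraction:
    """Positions + energies awaiting sequences to materialize nucleotides."""

    def __init__(self, positions, e_hybrid, ed_a, ed_b, e_total):
        self.positions = positions
        self.e_hybrid = e_hybrid
        self.ed_a = ed_a
        self.ed_b = ed_b
        self.e_total = e_total

    def bind(self, seq_a: RnaSequence, seq_b: RnaSequence) -> Interaction:
        for (i, j) in self.positions:
            if i >= len(seq_a) or j >= len(seq_b):
                raise InvalidInputError(
                    f"external pair ({i + 1},{j + 1}) outside sequences "
                    f"{seq_a.id}/{seq_b.id}"
                )
        pairs = tuple(
            BasePair(i, j, seq_a.residues[i], seq_b.residues[j])
            for (i, j) in self.positions
        )
        return Interaction(
            pairs=pairs,
            e_hybrid=self.e_hybrid,
            ed_a=self.ed_a,
            ed_b=self.ed_b,
            e_total=self.e_total,
        )


class ExternalPredictor:
    """Serve precomputed interactions through the predictor interface.

    Records are looked up by (id_a, id_b); multiple records per pair form
    the energy-sorted suboptimal list.  Asking for a sequence combination
    absent from the table raises :class:`PredictionError` naming the ids,
    so missing mutant predictions fail loudly instead of silently counting
    as no interaction.  A pair can be declared interaction-free by listing
    it in ``no_interaction``.
    """

    def __init__(
        self,
        records: list[tuple[str, str, "_LazyInteraction"]],
        no_interaction: Optional[set[tuple[str, str]]] = None,
    ) -> None:
        self._by_pair: dict[tuple[str, str], list[_LazyInteraction]] = defaultdict(list)
        for id_a, id_b, lazy in records:
            self._by_pair[(id_a, id_b)].append(lazy)
        for lst in self._by_pair.values():
            lst.sort(key=lambda r: r.e_total)
        self._none = no_interaction or set()

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExternalPredictor":
        return cls(parse_external_interactions(path))

    def _lookup(self, a: RnaSequence, b: RnaSequence) -> list["_LazyInteraction"]:
        key = (a.id, b.id)
        if key in self._none:
            return []
        if key not in self._by_pair:
            raise PredictionError(
                f"no external prediction for pair ({a.id!r}, {b.id!r})"
            )
        return self._by_pair[key]

    def mfe(self, a: RnaSequence, b: RnaSequence, region=None) -> Optional[Interaction]:
        records = self._lookup(a, b)
        return records[0].bind(a, b) if records else None

    def suboptimals(
        self, a: RnaSequence, b: RnaSequence, max_count: int, region=None
    ) -> list[Interaction]:
        return [r.bind(a, b) for r in self._lookup(a, b)[:max_count]]
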