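"""Seeded synthetic sequence pairs with a known implanted interaction site.

The generator emulates the sRNA-vs-mRNA-context setup used for CoM design:
sequence B carries the reverse complement of a contiguous site inside
sequence A (optionally degraded to G-U wobbles), embedded in random flanks.
Flanks are rejection-sampled so that no stretch of >= 3 consecutive
antiparallel pairable positions forms between a flank and the partner's
site, keeping the implanted site the dominant interaction.  All output is
reproducible from (spec, seed).
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .errors import FixtureError, InvalidInputError
from .interactions import BasePair
from .sequence import RnaSequence, is_pairable, reverse_complement

#: Rejection-sampling retry cap per flank.
MAX_FLANK_RETRIES = 1000

_GC = "GC"
_AU = "AU"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic interacting pair.

    site_length: implanted complementary pairs; gc_fraction: probability a
    site position is G/C; wobble_fraction: probability a site pair is
    degraded to a wobble (only where a single change in B yields G-U/U-G);
    flank lengths are per side of the site, in nt.
    """

    site_length: int = 7
    gc_fraction: float = 0.8
    flank_length_a: int = 15
    flank_length_b: int = 15
    wobble_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.site_length < 1:
            raise InvalidInputError("site_length must be >= 1")
        for frac in (self.gc_fraction, self.wobble_fraction):
            if not 0.0 <= frac <= 1.0:
                raise InvalidInputError("fractions must be in [0, 1]")
        if self.flank_length_a < 0 or self.flank_length_b < 0:
            raise InvalidInputError("flank lengths must be >= 0")


@dataclass(frozen=True)
class InteractingPair:
    """A generated pair with its implanted ground truth."""

    seq_a: RnaSequence
    seq_b: RnaSequence
    site_start_a: int  # 0-based start of the site in A
    site_start_b: int  # 0-based start of the (reverse-complementary) site in B
    implanted_pairs: tuple[BasePair, ...]


def _random_site(rng: random.Random, spec: FixtureSpec) -> str:
    return "".join(
        rng.choice(_GC) if rng.random() < spec.gc_fraction else rng.choice(_AU)
        for _ in range(spec.site_length)
    )


def _register_is_unique(site_a: str, site_b: str, min_run: int = 3) -> bool:
    """True if no shifted register of site_a against site_b can stack.

    The implanted register pairs a[k] with b[n-1-k], i.e. lies on the
    antidiagonal i + j = n - 1; any pairable run of >= min_run off that
    antidiagonal would give the pair an alternative site register, breaking
    the single-site ground truth the generator promises.
    """
    n = len(site_b)
    for i in range(len(site_a)):
        for j in range(n):
            if i + j == n - 1:
                continue  # runs stay on their own antidiagonal
            run = 0
            while (
                i + run < len(site_a)
                and j - run >= 0
                and is_pairable(site_a[i + run], site_b[j - run])
            ):
                run += 1
                if run >= min_run:
                    return False
    return True


def _find_offending_run(
    res_a: str,
    res_b: str,
    site_a0: int,
    site_b0: int,
    n: int,
    min_run: int = 3,
) -> Optional[list[tuple[int, int]]]:
    """Cells of a maximal pairable run >= min_run off the implanted register.

    Antiparallel runs stay on one antidiagonal i + j = const; the only run
    allowed to reach min_run is the implanted site itself (antidiagonal
    ``site_a0 + site_b0 + n - 1``, inside the site windows).  Off-register
    runs that touch flank cells are already offending at length 2: a single
    site mutation can otherwise bridge such a run with the site remnant
    into a competing composite interaction, breaking the single-site
    ground truth.  Returns None when the implanted register is the unique
    stackable interaction.
    """
    c0 = site_a0 + site_b0 + n - 1
    la, lb = len(res_a), len(res_b)
    for i in range(la):
        for j in range(lb - 1, -1, -1):
            if 0 < i and j + 1 < lb and is_pairable(res_a[i - 1], res_b[j + 1]):
                continue  # not the start of a maximal run
            run = 0
            while (
                i + run < la
                and j - run >= 0
                and is_pairable(res_a[i + run], res_b[j - run])
            ):
                run += 1
            if run < 2:
                continue
            cells = [(i + t, j - t) for t in range(run)]
            on_site = i + j == c0 and all(
                site_a0 <= x < site_a0 + n and site_b0 <= y < site_b0 + n
                for x, y in cells
            )
            touches_flank = any(
                not (site_a0 <= x < site_a0 + n) or not (site_b0 <= y < site_b0 + n)
                for x, y in cells
            )
            if on_site:
                continue
            if run >= min_run or touches_flank:
                return cells
    return None


def _repair_flanks(
    rng: random.Random,
    res_a: list[str],
    res_b: list[str],
    site_a0: int,
    site_b0: int,
    n: int,
) -> None:
    """Resample flank residues (seeded) until no off-register run remains.

    Every offending run contains at least one flank position (within-site
    off-register runs are excluded by the site's own uniqueness check), so
    resampling one such position per iteration converges quickly.
    """
    budget = 50 + 10 * (len(res_a) + len(res_b))
    for _ in range(budget):
        cells = _find_offending_run(
            "".join(res_a), "".join(res_b), site_a0, site_b0, n
        )
        if cells is None:
            return
        flank_cells = [
            (seq_idx, pos, partner)
            for (x, y) in cells
            for seq_idx, pos, lo, hi, partner in (
                (0, x, site_a0, site_a0 + n, res_b[y]),
                (1, y, site_b0, site_b0 + n, res_a[x]),
            )
            if not lo <= pos < hi
        ]
        seq_idx, pos, partner = rng.choice(flank_cells)
        # replace with a residue that cannot pair the partner cell, so the
        # found run is destroyed for sure and the walk cannot cycle in place
        choices = [nt for nt in "ACGU" if not is_pairable(nt, partner)]
        (res_a if seq_idx == 0 else res_b)[pos] = rng.choice(choices)
    raise FixtureError(f"could not de-complement flanks within {budget} repairs")


def generate_interacting_pair(spec: FixtureSpec) -> InteractingPair:
    """Generate one seeded pair with a single implanted complementary site."""
    rng = random.Random(spec.seed)
    n = spec.site_length
    fa, fb = spec.flank_length_a, spec.flank_length_b
    for _ in range(MAX_FLANK_RETRIES):
        site_a = _random_site(rng, spec)
        site_b_list = list(reverse_complement(site_a))
        # degrade selected pairs to G-U wobbles where a single change in B works
        for k in range(n):  # k indexes the site position in A
            if rng.random() < spec.wobble_fraction:
                if site_a[k] == "G":
                    site_b_list[n - 1 - k] = "U"
                elif site_a[k] == "U":
                    site_b_list[n - 1 - k] = "G"
        site_b = "".join(site_b_list)
        if n >= 3 and not _register_is_unique(site_a, site_b):
            continue
        res_a = [rng.choice("ACGU") for _ in range(fa)] + list(site_a) + [
            rng.choice("ACGU") for _ in range(fa)
        ]
        res_b = [rng.choice("ACGU") for _ in range(fb)] + list(site_b) + [
            rng.choice("ACGU") for _ in range(fb)
        ]
        try:
            # some sites leave a junction cell with no non-pairing residue;
            # those fixtures are discarded and the site resampled
            _repair_flanks(rng, res_a, res_b, fa, fb, n)
        except FixtureError:
            continue
        break
    else:
        raise FixtureError(
            f"no single-register fixture found within {MAX_FLANK_RETRIES} "
            "attempts (site_length/gc_fraction too extreme?)"
        )
    start_a, start_b = fa, fb
    residues_a = "".join(res_a)
    residues_b = "".join(res_b)
    pairs = tuple(
        BasePair(
            pos_a=start_a + k,
            pos_b=start_b + n - 1 - k,
            nt_a=residues_a[start_a + k],
            nt_b=residues_b[start_b + n - 1 - k],
        )
        for k in range(n)
    )
    return InteractingPair(
        seq_a=RnaSequence(id=f"synthA_{spec.seed}", residues=residues_a),
        seq_b=RnaSequence(id=f"synthB_{spec.seed}", residues=residues_b),
        site_start_a=start_a,
        site_start_b=start_b,
        implanted_pairs=pairs,
    )


def _interior_gc_pairs(pair: InteractingPair) -> list[BasePair]:
    """Implanted GC/CG pairs that stack on both sides within the site."""
    inner = pair.implanted_pairs[1:-1]
    return [bp for bp in inner if {bp.nt_a, bp.nt_b} == {"G", "C"}]


def generate_known_com_table(
    n_pairs: int,
    template: Optional[FixtureSpec] = None,
    seed: int = 0,
    out_csv: Optional[str | Path] = None,
) -> list[dict]:
    """Generate records of (sequence pair, known CoM) with ground truth.

    Each record's known CoM is the flip of a randomly chosen interior GC
    pair of the implanted site; fixtures whose site lacks interior GC pairs
    are regenerated with a derived seed.  Returns the records as dicts in
    the benchmark table schema (1-based coordinates) and optionally writes
    them as CSV.
    """
    if n_pairs < 1:
        raise InvalidInputError("n_pairs must be >= 1")
    template = template if template is not None else FixtureSpec()
    rng = random.Random(seed)
    records: list[dict] = []
    for idx in range(n_pairs):
        for attempt in range(MAX_FLANK_RETRIES):
            sub_seed = rng.randrange(2**31)
            spec = FixtureSpec(
                site_length=template.site_length,
                gc_fraction=template.gc_fraction,
                flank_length_a=template.flank_length_a,
                flank_length_b=template.flank_length_b,
                wobble_fraction=template.wobble_fraction,
                seed=sub_seed,
            )
            pair = generate_interacting_pair(spec)
            gc = _interior_gc_pairs(pair)
            if gc:
                break
        else:
            raise FixtureError("no fixture with an interior GC pair found")
        bp = rng.choice(gc)
        records.append(
            {
                "pair_id": f"pair{idx + 1:03d}",
                "seq_a": pair.seq_a.residues,
                "seq_b": pair.seq_b.residues,
                "pos_a": bp.pos_a + 1,
                "pos_b": bp.pos_b + 1,
                "wt_bp": bp.nt_a + bp.nt_b,
                "mut_bp": bp.nt_b + bp.nt_a,
            }
        )
    if out_csv is not None:
        with open(out_csv, "w", newline="") as handle:
            writer = csv.DictWriter(handle, fieldnames=list(records[0].keys()))
            writer.writeheader()
            writer.writerows(records)
    return records
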