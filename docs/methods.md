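# Methods

## Scope and model assumptions

`comsel` designs single-base-pair compensatory mutations (CoMs) for
RNA–RNA interactions under two assumptions: the regulatory interaction is
a **single site** — one contiguous antiparallel stretch of inter-molecular
base pairs, not interrupted by intra-molecular structure — and the energy
model's most stable interaction identifies the relevant parts of that
site. Multi-site interactions (where a second site can compensate the loss
of the first) and multi-nucleotide CoMs are out of scope.

## Duplex energy model

An interaction is a chain of base pairs, strictly antiparallel
(positions increasing in A, decreasing in B), each pair drawn from the
canonical set plus the G·U wobble. Its energy is

    E_total = E_init + Σ step terms + ED_A(site_A) + ED_B(site_B)

* **Stacking**: consecutive pairs contribute the published Turner 2004
  RNA/RNA nearest-neighbor free-energy increments at 37 °C (kcal/mol), as
  distributed with ViennaRNA (`rna_turner2004.par`), embedded as a
  versioned 6×6 table over the pairable pair types. The table is
  symmetric under reading direction, which makes predictions invariant
  under swapping the two sequences' roles.
* **Loops/bulges**: up to `max_loop_side` (default 16) unpaired residues
  are allowed between consecutive pairs on either sequence, charged
  `base + per_unpaired·(g_a+g_b) + per_asymmetry·|g_a−g_b|` with defaults
  1.0 / 0.5 / 0.3 kcal/mol — an affine surrogate for the tabulated
  interior-loop model, coarse but monotone in loop size (enforced by
  requiring `per_unpaired ≥ per_asymmetry`).
* **Initiation**: +4.10 kcal/mol (Turner 2004 duplex initiation).
  Terminal AU/GU end penalties are omitted; the model is a comparative
  stability proxy, not an absolute free-energy calculator.
* **Accessibility (ED)**: the energetic cost of opening intra-molecular
  structure over the interacting windows, supplied by a provider:
  zero (default), constant per nucleotide, or a user TSV of per-window
  values. Partition-function EDs are deliberately not computed; users
  needing predictor-grade energies can feed precomputed interactions
  through the external adapter, which serves them behind the same
  predictor interface.
* Only favorable interactions (`E_total < 0`) are ever reported.

### Exact per-boundary optimization

Because ED depends only on the interaction's boundary windows, the solver
enumerates, for every boundary quadruple `(start_a, end_a, start_b,
end_b)`, the optimal chain with exactly those endpoints: a dynamic program
anchored at each possible 5′-most pair fills the optimal extension to
every 3′-most pair. This yields simultaneously the exact MFE under
arbitrary ED providers and the suboptimal list with **one interaction per
distinct boundary** (energy-sorted; ties broken by lexicographically
smallest boundary, making all outputs deterministic). The cost is
quadratic in the number of pairable position pairs; the implementation
targets site-scale inputs — tens of nucleotides per sequence, e.g. an
sRNA region against a window around a start codon — not genome scans.

A brute-force oracle (exhaustive recursive enumeration of all valid
chains, guarded to ≤ 12 nt per sequence) shares the parameter tables but
nothing else with the dynamic program; the test suite checks exact
energy agreement on hundreds of seeded random pairs, with and without
accessibility penalties.

## Candidate generation

Base pairs are collected from the wildtype MFE interaction (rank 1), and
optionally from suboptimal interactions restricted to the MFE's site
windows, de-duplicated by position with the best source rank kept. Helix
context is classified per pair — stacked on both sides, helix end (one
side), or lonely (no stacking neighbor) — using the interaction the pair
was collected from; when a pair occurs in several, the MFE's context wins.
Default filters keep all six pair types and drop lonely pairs (they
contribute little stability, so mutating them proves little); helix-end
exclusion is available as a flag.

Mutant pairs must be pairable, differ from the wildtype, and be
**non-compatible**: the mutant nucleotide in A must not pair the wildtype
nucleotide in B and vice versa, counting G·U as pairing. Flip mode
returns the nucleotide swap; all-alternatives mode returns every
non-compatible pairable pair — exactly three per wildtype type (e.g. for
U–A: G–U, G–C, A–U; C–G is excluded because wildtype U wobble-pairs
mutant G). Flip is the default: it is the common choice in practice and
keeps wildtype-only and mutant-only stabilities similar.

## Evaluation and ranking

Each candidate is evaluated on ww, wm, mw, mm (first letter = sequence A
state; ww is computed once per pair). A combination with no favorable
interaction enters the arithmetic as 0 kcal/mol — "maximally
destabilized" — and is flagged explicitly in the output, which keeps all
statistics defined.

* `mfeCover`: the mutated base pair must be present in the mm MFE
  interaction. This is the strict reading; mere overlap of the mm site
  with the mutated positions does not pass. Rationale: if the double
  mutant pairs elsewhere, recovery of the in vitro signal would not
  demonstrate the intended base pair.
* `E(α, β)`: `MFE(ww) < 0`, `MFE(mm) < 0`,
  `MFE(ww) + α < min(MFE(mw), MFE(wm))`,
  `MFE(mm) + β < min(MFE(mw), MFE(wm))`; strict inequalities; defaults
  α = 2, β = 1 kcal/mol. wm/mw are not themselves required to be
  below zero.
* Sorting: `minDeltaE = min(MFE(mw), MFE(wm)) − max(MFE(ww), MFE(mm))`,
  descending.

Ranking is hierarchical with prefix semantics: a candidate's stratum is
the length of the longest prefix of the classifier chain it satisfies
(default chain `mfeCover, E`), so failing an early classifier forfeits
credit for later ones. Within a stratum candidates sort by minDeltaE;
remaining ties break by position in A, then lexicographic mutant pair —
an arbitrary but documented rule that makes output byte-deterministic.

## Benchmark harness

The harness consumes CSV tables of (sequence pair, known CoM) records and
produces tidy tables (no plots):

* **mutation-type tally** — classes with both pairs lex-sorted
  (AU→CG and UA→GC both count as `AUCG`);
* **interaction rank** — the 1-based index of the first energy-sorted
  interaction containing a known CoM base pair;
* **energy profiling** — for records whose MFE contains the known CoM,
  the known GC flip against a background of all other GC pairs of the
  same MFE treated as flips: four MFEs, five pairwise differences and
  minDeltaE per observation, Welch two-sample tests (known vs background
  per combination; two-tailed, unequal variance, unpaired) and paired
  t-tests per difference column. Tests run through scipy; the suite
  re-derives the p-values from the Welch/Satterthwaite and paired-t
  formulas directly as an independent check. Groups with fewer than two
  observations report NaN.
* **α/β sweep** and **classifier/sorter comparison** — candidate
  generation restricted to GC flips of the MFE pairs; combination
  energies are computed once per candidate and reused across the whole
  grid, so sweeps cost no additional predictions. Per cell/config the
  harness reports the count of valid candidates ranked not worse than the
  known CoM; records whose known CoM is not generated or fails the
  constraints are excluded from the mean and counted separately as
  failures.

## Synthetic fixtures

The generator emulates the sRNA-vs-mRNA-context setup: sequence B carries
the reverse complement of a contiguous site of sequence A (optionally
degraded to G·U wobbles where a single change in B suffices, i.e. at
site positions holding G or U in A), embedded in random flanks. Defaults:
site length 7, GC fraction 0.8 ("GC-rich, not homopolymeric"), 15-nt
flanks per side, no wobbles.

The generator's contract is that the implanted register is the **unique**
stackable interaction between the two sequences, so the implanted pair
list is genuine ground truth. Two seeded rejection/repair mechanisms
enforce this on the assembled sequences: (i) no antiparallel pairable run
of ≥ 3 anywhere off the implanted register — including runs crossing the
flank/site junctions and shifted registers of the site against itself —
and (ii) no off-register run of ≥ 2 touching a flank position, because a
single site mutation could otherwise bridge such a run with the site
remnant into a competing composite interaction. Offending flank positions
are re-drawn from residues that cannot pair their counterpart (a directed
repair that cannot cycle); sites whose junction admits no repair are
resampled. All outputs are reproducible from (spec, seed); retry caps are
documented constants.

What the fixtures do **not** emulate: intra-molecular structure and
realistic accessibility profiles, heterogeneous site conservation,
protein-dependent interactions, and the shifted-register ambiguity of
repetitive natural sites (excluded by construction). Passing the
recovery tests therefore shows the selector's machinery is correct under
clean single-site conditions, not that predictions on arbitrary natural
sequences are reliable — for those, interaction prediction quality is the
binding constraint, and the external adapter exists precisely to plug in
a stronger predictor.

## Numerical choices and problem sizes

Energies are plain floats; sort keys round to 10⁻⁹ kcal/mol before
tie-breaking so equal-energy interactions order by boundary. Coordinates
are 0-based internally and 1-based inclusive in every file and CSV.
The test suite verifies the dynamic program against the brute-force
oracle at sequence lengths 4–12 (hundreds of seeded pairs) and runs the
recovery and harness checks on fixtures with 6-bp sites and 3-nt flanks —
12-nt sequences, chosen so every prediction in those tests is
oracle-verifiable — and larger 8-bp/20-nt-flank fixtures for site
recovery. Known limitations: the affine loop model and missing end
penalties bias absolute energies; rankings, which compare combinations of
the same site, are robust to this but not immune; and the per-boundary
solver is intentionally exhaustive, so very long inputs are slow —
restrict to the relevant windows first.
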