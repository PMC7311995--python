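# comsel

Compensatory-mutation selection for RNA–RNA interaction (RRI) verification
experiments.

Regulatory RNAs — bacterial sRNAs, miRNAs — act through direct base pairing
with their target RNAs. A predicted interaction is verified in vitro with a
*compensatory mutation* (CoM): one nucleotide in each RNA is mutated so
that each wildtype–mutant combination loses a base pair of the interaction
site while the double mutant restores it. Picking the mutation is the hard
part: a weak choice leaves the mixed combinations almost as stable as the
wildtype and the experiment shows nothing. `comsel` turns that ad hoc
decision into a ranked list.

## What it computes

For two RNAs A and B, `comsel`:

1. predicts the most stable interaction of the wildtype pair under a
   nearest-neighbor duplex model (Turner 2004 stacking increments, affine
   interior-loop/bulge penalties, pluggable accessibility penalties
   ED ≥ 0, total energy `E = E_hybrid + ED_A + ED_B`, only `E < 0`
   reported);
2. collects its inter-molecular base pairs (optionally also those of
   suboptimal interactions inside the same site), filters them by pair
   type and helix context (lonely / helix-end / stacked), and generates
   mutant pairs — either the nucleotide *flip* (GC → CG) or all three
   non-compatible alternatives, where "non-compatible" counts the G·U
   wobble as pairing;
3. evaluates every candidate on the four sequence combinations
   ww, wm, mw, mm (first letter = state of A) and ranks them through a
   classifier hierarchy:
   - **mfeCover** — the mutated base pair must reappear in the mutant-only
     (mm) MFE interaction;
   - **E** — `MFE(ww) + α < min(MFE(mw), MFE(wm))` and
     `MFE(mm) + β < min(MFE(mw), MFE(wm))`, with `MFE(ww), MFE(mm) < 0`
     (defaults α = 2, β = 1 kcal/mol);
   - sorting by **minDeltaE** `= min(MFE(mw), MFE(wm)) −
     max(MFE(ww), MFE(mm))`, descending — the top candidate destabilizes
     both mixed combinations the most.

A benchmark harness reproduces the supporting analyses over tables of
known CoMs (mutation-type tallies, rank of the CoM-containing interaction,
energy profiling with Welch and paired t-tests, α/β threshold sweeps,
classifier/sorter comparisons), and a seeded synthetic-fixture generator
provides ground-truth data. Every energy the dynamic program reports is
testable against a brute-force enumeration oracle on short sequences.

## Worked example

Generate a synthetic sRNA-like pair with one implanted 7-bp site and rank
flip mutations of its base pairs:

```sh
comsel fixtures --n-pairs 1 --site-length 7 --gc-fraction 0.8 \
    --flank-a 10 --flank-b 10 --seed 3 --out-prefix demo
comsel rank \
    --query  AAAAAAAAAAGGGCCGCAAGACAAAGA \
    --target CAAGAAAAAAGCGGCCCAAGAAAAAAC \
    --out ranked.csv
# wrote 7 ranked candidates to ranked.csv
```

`ranked.csv` (coordinates 1-based; energies kcal/mol, 2 decimals):

```
rank,pos_a_1based,pos_b_1based,wt_bp,mut_bp,context,mfe_ww,mfe_wm,mfe_mw,mfe_mm,mfeCover,E_pass,minDeltaE,none_ww,none_wm,none_mw,none_mm
1,15,13,CG,GC,stacked_both,-15.00,-7.30,-7.30,-15.00,True,True,7.70,False,False,False,False
2,13,15,GC,CG,stacked_both,-15.00,-7.50,-7.50,-15.00,True,True,7.50,False,False,False,False
3,14,14,CG,GC,stacked_both,-15.00,-7.50,-7.50,-15.00,True,True,7.50,False,False,False,False
4,16,12,GC,CG,stacked_both,-15.00,-9.20,-9.20,-15.80,True,True,5.80,False,False,False,False
5,12,16,GC,CG,stacked_both,-15.00,-8.40,-8.40,-14.20,True,True,5.80,False,False,False,False
6,17,11,CG,GC,helix_end,-15.00,-11.60,-11.60,-14.90,True,True,3.30,False,False,False,False
7,11,17,GC,CG,helix_end,-15.00,-11.70,-11.70,-14.10,True,True,2.40,False,False,False,False
```

Read: the wildtype interaction is stable at −15.0 kcal/mol; flipping the
central C–G pair (position 15 of A with 13 of B) raises both mixed
combinations to −7.3 while the double mutant recovers −15.0, the strongest
and most symmetric destabilization pattern (minDeltaE = 7.7) — the best
bet for a verification experiment. Helix-end flips rank last: a mixed
combination keeps most of its stability, so a lost in vitro signal would
be ambiguous.

The benchmark harness runs on the same table format the fixture command
writes:

```sh
comsel benchmark --table demo.csv --analysis rank  --out ranks.csv
comsel benchmark --table demo.csv --analysis sweep --out sweep.csv
```

Precomputed interactions from another predictor can replace the built-in
model via `--predictor external:<csv>` (see `comsel.fileio` for the
format); accessibility penalties come from `--acc const:<v>` or
`--acc table:<tsv>`.

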