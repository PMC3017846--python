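# Methods

This note records the models, parameter choices and numerical
conventions behind `mircane`, and what the synthetic benchmarks do and
do not demonstrate.

## Sequence model and coordinates

All sequences are normalised to RNA (`T→U`) on input; IUPAC ambiguity
codes collapse to `N`, which never pairs, never matches in the scan, and
counts toward length but not toward G+C.  Library coordinates are
0-based half-open; report tables are 1-based inclusive (miRBase
convention).  FASTA output wraps at 60 columns for reproducible files.

## Homology scan

The scan finds every occurrence of a mature query in a database sequence
within a unit-cost edit distance (substitutions plus single-nucleotide
indels; a 2-nt gap costs 2) of at most `max_edits` (default 3), on both
strands.  Implementation is seed-and-extend with pigeonhole seeding: the
query is partitioned into `max(max_edits+1, ceil(L/seed_len))` disjoint
covering words, so any alignment with ≤ `max_edits` errors contains one
word verbatim and seeding is lossless.  `seed_len` (default 7, the
classic BLASTN word size) is an upper bound on word length — exact
7-mers alone would not be lossless for 21-nt queries at 3 edits, since
the longest guaranteed exact stretch is ⌈(21−3)/4⌉ = 5 nt.  Candidate
offsets are verified by a banded DP whose cost encodes (edit total, gap
moves) lexicographically, preferring substitutions over indels among
co-optimal alignments and the smallest end among co-optimal ends.
Overlapping hits of one query/strand merge keeping the lowest edit
total, ties to the leftmost.  A brute-force oracle
(`mircane.oracles.scan_oracle`) re-derives the hit set by running the
same banded DP at *every* offset with vectorised numpy, sharing no code
with the seeded path; equality is property-tested and re-checked by the
acceptance script.  E-values are not computed: the 0–3 edit rule is the
only gate the published protocol actually applied to candidates.

Low-complexity filtering is not applied (the original pipeline used
BLAST's filter only to bound search cost); records with homopolymer
fraction > 0.8 are logged as warnings instead.

The exclusion screen is a local stand-in for tRNA/rRNA/snoRNA database
screens: any window whose mature-spanning region hits a user-supplied
exclusion FASTA under scan semantics is dropped and logged.

## Folding model

The built-in folder is a Nussinov-style maximum-weight nested-pairing
dynamic program: every admissible pair contributes a fixed weight
(G:C −3, A:U −2, G:U −1 "kcal/mol"), hairpin loops span at least
`min_loop` = 3 unpaired bases, pseudoknots are excluded, and the optimum
minimises the summed weight.  Ties break deterministically: scanning
left to right, a position is paired whenever some co-optimal structure
pairs it, with the smallest partner index (tie-break exactness relies on
the weights being small integers; exotic fractional weights could tie
inexactly in float arithmetic).  The fill runs under numba; traceback is
plain Python.  Lone pairs are always permitted — the published criteria
do not forbid them — and no option to forbid them is provided (a
two-state DP would be needed; known limitation).

This is **not** a thermodynamic nearest-neighbour model.  Its energies
are systematically more negative than mfold/RNAfold values, so MFEI
values computed under it are not numerically comparable to published
thermodynamic MFEIs (the worked example shows built-in MFEIs of 2–3
where mfold-based studies report ~1.0).  Published MFEI statistics are
therefore reproduced from the bundled catalog's printed values, not by
refolding.  For fidelity to thermodynamic folding the pipeline ingests
external structures (Vienna dot-bracket or CT connect files, first
structure per file; a file-supplied energy is used as-is) and exposes
the MFEI cutoff as configuration.  A brute-force enumeration oracle
(plain recursion over all nested structures, no memoisation) certifies
the DP on sequences up to 30 nt.

AMFE = (|MFE|/length)·100 and MFEI = AMFE/GC% are reported as positive
numbers, matching the sign convention of published precursor tables.

## Hairpin validation

Nine criteria gate a candidate (defaults in brackets, all configurable):

| # | check | default |
|---|-------|---------|
| c1 | mature/star duplex lies on one stem | — |
| c2 | mature within one arm (not spanning the loop) | — |
| c3 | mature on the homolog's arm | auto-pass if unknown |
| c4 | duplex mismatches within bounds | 1–6 |
| c5 | star unbroken (no star-side bulges) | — |
| c6 | MFEI > cutoff, MFE < 0, GC% in range | 0.65, 30–70% |
| c7 | max consecutive mismatches | ≤ 2 |
| c8 | paired duplex bases | ≥ 2 |
| c9 | trimmed stem-loop length | ≥ 60 nt |

Precise semantics (the published wording leaves room, and these
readings make the criteria independently testable):

* a mature position is a **mismatch** when unpaired, *except* positions
  inside a terminal hairpin loop (nearest paired neighbours pair each
  other) — loop nucleotides face no star and are not scored against it;
  dangling ends do count as mismatches;
* the **star span** is the interval between the outermost partners of
  paired mature positions; **c1** fails if any non-mature position in
  the span pairs outside the mature (a branch interrupting the stem),
  and **c5** fails if the span contains more unpaired positions than the
  mature has mismatches (i.e. star-side bulges beyond the gaps that face
  mature mismatches);
* **c4**'s lower bound of one mismatch is enforced literally (a perfect
  duplex is rejected) but exposed as `min_duplex_mismatches` since
  perfect duplexes are biologically plausible;
* **c8** is literal: at least two paired bases in the duplex;
* no 2-nt 3'-overhang correction is applied when inferring the star;
  the star is the span of partners;
* GC bounds are inclusive; the MFEI bound is strict (> 0.65).

The **trimmed stem-loop** is the minimal well-formed hairpin containing
mature, star and loop: starting from the duplex span, enclosing base
pairs are adopted outward as long as no branch intervenes (interior
loops and bulges are crossed; a paired position between the current span
and the enclosing partner stops the walk).  GC%, MFE, AMFE, MFEI and the
c9 length are evaluated on this trimmed region — published precursor
lengths (94–411 nt, far below the 620-nt scan window) show the protocol
likewise reported a trimmed precursor.  For built-in structures the
trimmed MFE is the weight sum over pairs inside the region; an external
file's energy, when present, is used directly.

Every criterion is *independently* falsifiable: the synthetic module
constructs, for each criterion, a candidate failing exactly that one
(e.g. for c1, a mature paired across two stems separated by a branch
hairpin; for c2, a self-complementary mature spanning its own terminal
loop; for c8, a single G:C pair with the rest of the mature inside a
large terminal loop enclosed by a strong extension stem).  Under naive
criterion readings several of these knockouts are logically impossible —
fewer than two pairs forces the mismatch count out of the c4 range —
which is what motivated the loop-exclusion rule above.

Candidates that match a query with ≤ 1 edit yet fail validation are
logged as near-misses (the homology-strong-but-unfoldable case that EST
truncation produces; such loci are published only after manual review).

## Redundancy

Identity is global Needleman–Wunsch (match +1, mismatch −1, gap −2, via
Biopython's PairwiseAligner), 100·matches/alignment-length; clustering
is single-linkage; the representative is the longest member (ties:
lexicographically smallest id).  Precursor collapse uses strict
`> 95%`, target collapse non-strict `≥ 95%`, following the protocol's
two wordings.  Precursor identity is strand-agnostic (maximum over the
two orientations of one sequence), as BLAST-based redundancy screening
would be.  Before identity clustering, accepted candidates whose trimmed
stem-loops overlap on the same database record merge into one locus:
the plus- and minus-strand scans both recover a good hairpin (the star
arm matches the query within the edit budget whenever the designed
mismatch count is small), and the two views of one hairpin are the same
locus by construction.  Identity defaults to the trimmed precursor
region rather than the full EST.

## Target prediction

The block pre-filter slides the miRNA 5'→3' over every same-length
sense-strand window: positions 1–8 (block 1, ≤ 2 mismatches), 9–11
(block 2, 0 mismatches — spanning the cleavage site opposite miRNA
position 10, the orientation consistent with 5'RACE-mapped cleavage),
and 12–end (block 3, ≤ 3; non-21-mers absorb the length difference in
block 3).  G:U counts as a block mismatch by default
(`gu_is_block_match` inverts this): the filter text speaks only of
mismatches, and the wobble is rewarded later by its reduced penalty.

Passing windows (and windows up to `max_bulges` = 2 nt longer/shorter)
are rescored by a DP minimising the antiparallel duplex penalty:
Watson–Crick 0, G:U wobble **pair** 0.5 (the "G:U bulge (0.5)" of the
original scoring, distinct from the 1.5-point bulged nucleotide),
mismatch 1, bulged nucleotide 1.5.  At most `max_bulges` bulged
nucleotides are allowed in total, enforced as DP state: two bulges
already cost 3.0 of the 3.5 budget, so deeper bulging can never rescue a
site, and the hard cap makes the enumeration oracle (all gap-position
combinations) exact.  Scores use half-point integer arithmetic
internally, so comparisons are exact.  Sites scoring ≤ 3.5 are kept; one
hit is reported per (miRNA family, transcript cluster), best score
first.  Scanning is sense-strand only (messages are sense);
configurable in principle via reverse-complementing the input.

## Synthetic data

The generator emulates the study conditions at desk scale: by default 20
true precursors embedded among 200 decoys of 250–600 nt (154 random
uniform-composition sequences, 10 low-GC and 10 high-GC sequences, 10
tandem repeats, 10 MITE-like perfect terminal inverted repeats, and 6
structured decoys that carry a real catalog mature but fail validation —
a perfect inverted repeat of the mature, a GC-extreme hairpin, and an
undersized hairpin).  Embedded precursors use the 19 bundled catalog
matures on their annotated arms, designed duplex mismatch counts cycling
over the valid 1–6 range, terminal loops of 4–9 nt, extension stems that
push the trimmed hairpin past 60 nt, and random flanks of 120–280 nt so
records resemble EST lengths.

Constructions are letter-aware — designed mismatch columns, star bulges
and loops use nucleotides that cannot pair their surroundings, so the
maximum-weight fold equals the intended structure — and every construct
is verified at generation time by folding and checking it, redrawing
deterministically from the seeded stream on failure.  Planted target
sites are likewise verified: the recorded truth is the *effective*
optimum over the windows the scanner will consider, computed with the
enumeration oracle, because a site bulged near the miRNA 3' tail can
sometimes be matched more cheaply ungapped than through its designed
bulge.

What passing these benchmarks shows: the scan, folder, checker, scorer
and collapse behave exactly as specified on sequences where the ground
truth is knowable.  What it does not show: recovery rates on real ESTs,
whose precursors fold under thermodynamic rules, contain sequencing
errors, chimeras and truncations (the generator models none of these),
and whose decoy space is far richer than random sequence.  The
published corpus-level counts (19 precursors, 46 targets) depend on
2008-era database snapshots and are not reproducible at desk scale;
the bundled catalog's printed per-locus statistics are used instead for
the summary-level checks.

## Problem sizes and runtime

Oracle equivalence runs at 1000 random duplex pairs, 500 random folds
(lengths 10–30, where exhaustive enumeration is tractable) and 100 scan
instances (databases up to 5 kb); the end-to-end benchmark uses
20 embeds + 200 decoys.  The full test suite completes in about a
minute on one CPU, the acceptance script likewise.

## Known limitations

* Built-in folding energies are not thermodynamic; MFEI cutoffs
  calibrated on mfold transfer only qualitatively (use external
  structures for fidelity).
* Only the optimal structure is evaluated (external files: the first
  structure); suboptimal ensembles are out of scope.
* Lone base pairs cannot be forbidden.
* The 95% identity default applies to the trimmed precursor region, not
  the full EST.
* Target scanning is sense-strand only and reports one site per target
  cluster; multiple distinct sites on one transcript are collapsed to
  the best-scoring one.
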