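# Methods

## Model

DNA k-mers are identified with words over GF(2²) = {0, 1, α, α²} via
A↔0, C↔1, G↔α, T↔α².  Symbols are encoded as the integers 0–3 (α↦2,
α²↦3); under this encoding field addition is XOR of the 2-bit values and
multiplication is a 16-entry lookup table, so decoding runs branch-free in
cache.

A 4-ary (n, k) Hamming code is perfect iff n = (4ⁿ⁻ᵏ − 1)/3, which holds
exactly for (5, 3) and (21, 18); equivalently 3l + 1 must be a power of 4.
Perfection means the radius-1 Hamming balls around the 4ᵏ code words
partition the 4ⁿ word space into equivalence classes of size 3n + 1.
Syndrome decoding finds the class centre: s = z·Hᵀ; if s ≠ 0 it equals
t·(column j) of the parity-check matrix H for exactly one position j and
scalar t, and subtracting (XORing) t at position j yields the centre.
Requests of unsupported lengths fail with an error naming the 3l + 1
condition.

### Frozen matrices

* **H₅** has columns (1,1), (0,1), (1,0), (1,α), (1,α²).  This assignment
  reproduces every published worked decoding of the (5,3) code and is
  frozen; the order of the two unit columns is a convention (no worked
  example distinguishes them).  Check digits are positions 2–3 (1-based),
  information digits 1, 4, 5.
* **H₂₁** takes as columns the 21 projective points of GF(4)³ —
  normalised so the first nonzero entry is 1 — in lexicographic order of
  the base-4-encoded triples.  Check positions are chosen by greedy
  left-to-right rank selection (positions 1, 2, 6 in 1-based terms).

Any valid parity-check matrix yields the same counts, expectations and
formulas (they depend only on the perfect-code property); only per-word
class assignments differ, by a column permutation/scaling.

The short code packs the k information digits base-4, most significant
first by position; expanding a short code solves the check digits through
the inverse of the check submatrix.  Positions are 0-based in the API and
1-based in user-facing text.

## Key sets and accounting

For a query s and order n the key set is K_n(s) = {c(w) : d_H(w, s) ≤ n},
computed by decoding the cumulative neighbourhood and deduplicating.
Completeness is immediate; exhaustive tests at l = 5 also establish
constancy per case (|K₁| = 1 or 7; deduplicated |K₂| = 31 or 23) and
minimality of K₁.  Gapped queries decode the 4^g substitution words;
gaps are allowed in the query only, never in the genome, and at most two
per seed.

The reference formula f(s, K) = Σ a_b x^b counts the words retrievable
through K at each distance b from s.  It is computed by walking the
3n + 1 members of every key's class (classes are disjoint, so this is
exact and never scans 4ⁿ words); for gapped queries the distance is taken
over non-gap positions, i.e. the minimum over substitutions.  The sum
rule Σ a_b = (3n + 1)·|K| is asserted throughout.

### Two accountings for two-mismatch queries

The published four-type analysis of K₂ for a non-code word tallies the
1-mismatch keys (types 1–2), then one class per three remaining exact-2
words (type 3), then the classmates' key sets ∪_u K₁(u) − {c(s)}
(type 4) — *independently per type*.  Types 3 and 4 overlap (4 classes at
l = 5, 20 at l = 21), so this tally — 27 = 7+8+12 at l = 5,
611 = 31+520+60 at l = 21 — exceeds the deduplicated key-set size (23,
591).  Both quantities are real: the tally is the reference bill of the
per-type lookup strategy, the deduplicated count is what this package's
mapper spends.  `mismatch2_type_tally` computes the former,
`key_set_mismatch` the latter, and every report prints both.  The same
structure explains the published non-code-word 2-mismatch formulas, which
equal the idealised per-type profiles summed without cross-type
deduplication; the computed class census differs in the tail coefficients
and both are printed.

### Expectations

Expected key counts are exact rationals; 2-decimal and percentage
renderings use round-half-up.  At l = 5 every expectation is an
exhaustive average (1024 words; 1280 one-gap and 640 two-gap patterns).
At l = 21 full enumeration is infeasible and unnecessary: key-set size is
constant within the code-word and non-code-word cases (the code's
automorphisms act transitively on each; asserted at run time on random
samples, 100 per case by default, and proven exhaustively at l = 5), so
the expectation is the case-weighted mean with exact weights 1/64 and
63/64.  For gaps the substitution set S is an affine coset spanned by the
parity-check columns at the gap positions; since any two (three) columns
are linearly independent, its 4^g syndromes are distinct, and S contains
a code word with probability exactly 4^g/4ⁿ⁻ᵏ.  At l = 5, two gaps, that
probability is 1 — the non-code-word case does not exist, which is why
the corresponding report cell carries a note instead of a formula.
Per-case gap key counts are measured over every gap-position choice with
sampled contexts plus one constructed code-word-containing context, and
asserted constant.

### Composite seeds (length 10 = 5 + 5)

Case proportions (both/first/second/neither half a code word) are exactly
(1, 15, 15, 225)/256 by half-independence, verified exhaustively.
Serialization keys are c(s₁)c(s₂) (one table, classes of 256 members);
per-case key counts 1/7/7/13 give expectation 12.25.  Parallelization
keeps two tables with keys c(s₁)s₂ and s₁c(s₂) (classes of 16); cost is
counted in hash references with per-table multiplicity — a key used in
both tables is two references — giving 2/8/8/14 and 13.25.  The padding
scheme appends literal flanking bases to the key with no code protection;
pad mismatches are handled by direct enumeration.  This is the minimal
faithful reading of the elongation sketch, which gives no analysis for
padding.  Only 5+5 composites are reported (no published figures exist
for other combinations); 2-mismatch composite queries are out of scope.

## The mapper

The genome (not the read set) is indexed: every stride-spaced ACGT-only
window is stored once under the short code of its class centre; windows
containing other characters are counted and skipped.  Storage keys are
computed in bulk with vectorised table lookups (syndrome, error fix and
digit packing are all integer XOR/shift operations on NumPy arrays).
Short codes index a Python dict: 4³ = 64 possible keys at l = 5, 4¹⁸ at
l = 21 — far too many to direct-address, hence the sparse map; the
contract is constant expected-time lookup either way.  `occupancy()`
reports distinct keys over key-space size (table-density reporting).

Queries compute the key set, probe one bucket per key (per table for
parallelization), and **verify** every candidate by recomputing its
distance to the query window — required because buckets hold whole
classes and over-deliver.  Candidates beyond the declared order are
returned separately as by-products when requested, never as hits.  Gap
queries accept a candidate iff it matches at every non-gap position.
Cost is counted in hash references, never candidates.  The plain-table
baseline (identity-keyed index, one reference per neighbourhood word) is
the oracle: hit-set equality is asserted against it and against an
index-free full scan.

Each read contributes its offset-0 seed window only; how multiple
windows per read should combine is unspecified in the source analysis,
so single-window seeding is used and extension is out of scope.  Reverse
complement is the caller's choice (`strand_mode` forward/both; symbol
complement is x ↦ 3 − x).  Coordinates are 0-based half-open; FASTA IDs
are the first whitespace-delimited header token.  The index persists as
a versioned TSV container that includes the genome text, so mapping
needs no second input.

## Synthetic data

`SyntheticSpec` defaults describe a small test locus for a 2011-era
short-read instrument: 10 kb i.i.d. genome at 41% GC (human-like), 1000
reads of 36 bp sampled uniformly with constant base quality, edits
planted at distinct positions inside the first seed window so that
seed-level recovery is decidable from the emitted truth table.  Gap
plants write `-` (an unknown base) into the read.  The generator is
driven by one seeded NumPy generator; identical spec + seed gives
byte-identical FASTA/FASTQ/TSV output.

What this does *not* emulate: repeats and low-complexity sequence
(uniform i.i.d. bases understate bucket collisions on real genomes),
sequencing-error profiles, indels outside the seed window, quality
signal, and N-runs.  Passing tests therefore demonstrate combinatorial
correctness and expected-cost behaviour under uniform queries, not
mapping accuracy on real libraries.

## Numerical and scale choices

Exact arithmetic (`fractions.Fraction`) carries all expectations;
renderings round half-up.  Mapping tests use 10–20 kb genomes, 200–1000
queries per order and 1000 plants — sizes at which the brute-force scan
oracle is itself exhaustive and fast.  The mean-lookup check uses the
exact mixture SD of |K₁| (≈1.452) and a 3-standard-error band over 1000
seeded uniform queries.  Sampled constancy assertions and length-21
representatives are drawn from seeded generators, so all reported
numbers are reproducible bit-for-bit.

## Known limitations and published-figure discrepancies

* No alignment extension, scoring, or SAM output; no simultaneous
  gaps + mismatches; no genome-side gaps; n ≥ 3 mismatch queries work by
  the same definition but are exercised only in property tests at l = 5.
* Published figures this package reproduces by annotation rather than
  assertion (the report prints both numbers in every case):
  * (21, 2-gaps) expected keys: printed 13.87, but the published
    per-case analysis itself (10 keys w.p. 16/64, else 16) gives 14.50.
  * (5, 2-mismatch) in-text ratio 25.5% vs tabulated/computed 25.7%;
    (21, 1-mismatch) in-text 30.25 vs tabulated/computed 30.53;
    (21, 1-gap) in-text 3.84 vs tabulated/computed 3.81.
  * The parallelization ratio: printed 44.1% matches division by 30
    rather than by the 31-word bill used in every other row (13.25/31 =
    42.7%).
  * The serialize Case-4 reference formula as printed sums to 3448 ≠
    13·256; the computed census is printed with the published vector
    annotated.  Gap-row and 2-mismatch non-code-word formula cells
    likewise differ from the computed census as described above.
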