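# phcmap

Perfect-Hamming-code equivalence-class hashing for mismatch- and
gap-tolerant short-read seeding.

## The problem

Hash-based read mappers file every length-*l* genome window under its own
k-mer and answer an *n*-mismatch query by probing every word in the query's
Hamming neighbourhood — Σᵢ C(l,i)·3ⁱ table references (16 for one mismatch
at l = 5, 1954 for two mismatches at l = 21). `phcmap` implements an
algebraic alternative: treat DNA k-mers as words over the four-element
field GF(4) = {0, 1, α, α²} (A↔0, C↔1, G↔α, T↔α²) and file each window
under the nearest code word of a 4-ary **perfect Hamming code**.

A q-ary (n, k) Hamming code is *perfect* when n = (qⁿ⁻ᵏ − 1)/(q − 1), so
the radius-1 balls around code words tile the whole word space.  Over GF(4)
this happens at (n, k) = (5, 3) and (21, 18): the 4ⁿ k-mers split into 4ᵏ
equivalence classes of 3n + 1 members, each consisting of a code word
("centre") and its 3n single-substitution neighbours.  Syndrome decoding —
s = z·Hᵀ, then cancel the single error the syndrome points at — finds the
centre of any word in four table-free steps.

The centre (or its k information digits, the **short code**, an integer in
[0, 4ᵏ)) is the hash key.  Because one bucket holds a whole class, the key
set

    K_n(s) = { c(w) : d_H(w, s) ≤ n }

covers the full n-mismatch neighbourhood with far fewer references: 6.625
expected keys instead of 16 (l = 5, one mismatch), 30.53 instead of 64
(l = 21).  Gapped queries (a read position of unknown base, written `-`)
are covered by decoding the 4^gaps substitution words: 3.25 expected keys
at l = 5, 3.81 at l = 21.  Longer seeds are built by **serialization**
(two codes back to back, keys c(s₁)c(s₂)) or **parallelization** (two
tables, each protecting one half — a pigeonhole scheme), with expected
1-mismatch costs 12.25 and 13.25 for 5+5 seeds.

Everything a bucket returns beyond the declared order is a *by-product*
(extra 2- and 3-mismatch candidates retrieved for free); the mapper
verifies every candidate by recomputing its distance, so hit sets equal
those of a brute-force scan.

The package provides the field/code machinery, key-set construction and
its full cost accounting (`table2` report, exact rationals), an end-to-end
demonstration mapper with a plain-table baseline, and a seeded synthetic
genome/read generator — no external data needed anywhere.

## Worked example

Keys needed to find every exact and 1-mismatch genome position of `AAAAG`:

```
$ phc keyset --n 5 --query AAAAG --mismatches 1
# query=AAAAG scheme=plain n_keys=7
# reference_formula: 1 + 15x + 42x^2 + 54x^3
table	key	short_code
0	AAAAA	0
0	AACTG	14
0	ACGAG	2
0	AGAGG	10
0	CATAG	18
0	GTAAG	34
0	TAACG	54
```

`AAAAG` is not a code word, so seven class centres are needed (a code-word
query would need one).  The reference formula is the census of everything
those seven buckets hold: the exact word, all 15 one-mismatch words, plus
42 two-mismatch and 54 three-mismatch by-products.  Averaged over all 1024
5-mers the expected cost is 1/16·1 + 15/16·7 = 6.625 references — 41.4% of
the 16 the plain table needs.

The same machinery decodes single words (`CAAAT` → centre `CAAGT`, short
code 27), answers gapped queries (`phc keyset --query A-A-A` → 10 keys),
and drives the pipeline:

```sh
phc simulate --genome-length 10000 --n-reads 1000 --mismatches 1 --seed 1 --out-prefix sim
phc build-index --genome sim.genome.fa --n 5 --out sim.phc
phc map --index sim.phc --reads sim.reads.fq --mismatches 1 --with-baseline --out hits.tsv
```

`hits.tsv` columns: `read_id, seq_id, offset, strand, distance,
byproduct_flag` (0-based half-open coordinates); `hits.tsv.stats.json`
records `phc_lookups`, `baseline_lookups`, their ratio (≈ 0.41 for this
setting), candidate/hit counts and index occupancy.  `phc table2` prints
the full efficiency report — expected keys, exact rationals, ratios and
reference formulas for every covered (length, condition) row, with
published-figure discrepancies annotated rather than corrected; `phc table`
regenerates the complete 1024-row 5-mer ↔ code-word table.

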