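"""PHC-keyed genome index: build, query, verify, and the plain-table baseline.

The index stores every length-l genome window exactly once, filed under the
short code of its equivalence-class centre — the table has at most 4ᵏ
distinct keys but no more entries than a plain k-mer table.  An n-mismatch
(or gap) query touches one bucket per element of its key set instead of one
per neighbourhood word; every retrieved candidate is then *verified* by
recomputing its distance to the query window, because a bucket holds a whole
equivalence class and therefore over-delivers (the higher-distance extras
are returned separately as by-products when asked for).

Cost is counted in hash references, never candidates.  The plain-table
baseline (direct neighbourhood enumeration against an identity-keyed table)
is the correctness oracle and the cost comparator: 16 references for an
l = 5 one-mismatch lookup, 1954 for l = 21 two-mismatch, versus the key-set
sizes of this module.

Coordinates are 0-based half-open; sequence IDs are the first
whitespace-delimited token of the FASTA header.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .gf4_code import (
    CodeLengthError,
    PhcCode,
    SymbolDomainError,
    Word,
    build_phc,
    dna_to_word,
    hamming,
)
from . import composite as comp
from .keysets import (
    GAP,
    gap_positions,
    gap_substitutions,
    key_set_gap,
    key_set_mismatch,
    neighborhood,
    neighborhood_size,
    parse_gapped,
)

_SYM_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _SYM_LUT[ord(_b)] = _i
    _SYM_LUT[ord(_b.lower())] = _i


def seq_to_symbols(seq: str) -> np.ndarray:
    """DNA text → int8 symbol array; non-ACGT characters become −1."""
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    return _SYM_LUT[raw]


def revcomp(word: Sequence[int]) -> tuple[int, ...]:
    """Reverse complement on symbols (A↔T, C↔G ⇒ x ↦ 3 − x); gaps stay gaps."""
    return tuple(s if s == GAP else 3 - s for s in reversed(word))


def _pack_literal(w: Sequence[int]) -> int:
    acc = 0
    for s in w:
        acc = (acc << 2) | s
    return acc


def _pack_cols(wins: np.ndarray) -> np.ndarray:
    acc = np.zeros(len(wins), dtype=np.int64)
    for j in range(wins.shape[1]):
        acc = (acc << 2) | wins[:, j].astype(np.int64)
    return acc


@dataclass(frozen=True)
class GenomePosition:
    seq_id: str
    offset: int
    strand: str = "+"


@dataclass(frozen=True)
class Hit:
    position: GenomePosition
    distance: int
    read_id: str = ""
    byproduct: bool = False


@dataclass
class LookupStats:
    phc_lookups: int = 0
    baseline_lookups: int = 0
    candidates_scanned: int = 0
    hits_returned: int = 0
    reads_processed: int = 0
    reads_skipped: int = 0

    def __iadd__(self, other: "LookupStats") -> "LookupStats":
        self.phc_lookups += other.phc_lookups
        self.baseline_lookups += other.baseline_lookups
        self.candidates_scanned += other.candidates_scanned
        self.hits_returned += other.hits_returned
        self.reads_processed += other.reads_processed
        self.reads_skipped += other.reads_skipped
        return self

    @property
    def lookup_ratio(self) -> float:
        return self.phc_lookups / self.baseline_lookups if self.baseline_lookups else float("nan")


# ---------------------------------------------------------------------------
# Key layouts (how each scheme turns windows and key words into table keys)
# ---------------------------------------------------------------------------

class _Layout:
    """Maps windows to storage keys and query key-words to per-table ints."""

    n_tables = 1

    def __init__(self, scheme: comp.CompositeScheme | None, code: PhcCode | None):
        self.scheme = scheme
        self.code = code

    @property
    def seed_length(self) -> int:
        return self.code.n if self.code else self.scheme.total_length

    def storage_keys(self, wins: np.ndarray) -> list[np.ndarray]:
        raise NotImplementedError

    def query_tables(self, window: Word, order: int) -> list[list[int]]:
        raise NotImplementedError


class _PlainLayout(_Layout):
    def storage_keys(self, wins):
        return [self.code.bulk_short_codes(wins)]

    def query_tables(self, window, order):
        if GAP in window:
            ks = key_set_gap(self.code, window)
        else:
            ks = key_set_mismatch(self.code, window, order)
        return [sorted(self.code.short_code(k) for k in ks.keys)]


class _SerializeLayout(_Layout):
    def storage_keys(self, wins):
        c1, c2 = self.scheme.parts
        sc1 = c1.bulk_short_codes(wins[:, : c1.n])
        sc2 = c2.bulk_short_codes(wins[:, c1.n:])
        return [(sc1 << (2 * c2.k)) | sc2]

    def _key_int(self, key: Word) -> int:
        c1, c2 = self.scheme.parts
        return (c1.short_code(key[: c1.n]) << (2 * c2.k)) | c2.short_code(key[c1.n:])

    def query_tables(self, window, order):
        if GAP in window:
            raise CodeLengthError("gap queries are supported on plain code seeds only")
        if order == 0:
            keys = [comp.serialize_key(window)]
        elif order == 1:
            keys = comp.serialize_keys_1mm(window).tables[0]
        else:
            raise ValueError("composite schemes support mismatch orders 0-1")
        return [sorted(self._key_int(k) for k in keys)]


class _ParallelizeLayout(_Layout):
    n_tables = 2

    def storage_keys(self, wins):
        c1, c2 = self.scheme.parts
        sc1 = c1.bulk_short_codes(wins[:, : c1.n])
        sc2 = c2.bulk_short_codes(wins[:, c1.n:])
        lit1 = _pack_cols(wins[:, : c1.n])
        lit2 = _pack_cols(wins[:, c1.n:])
        t1 = (sc1 << (2 * c2.n)) | lit2   # protected first half, literal second
        t2 = (lit1 << (2 * c2.k)) | sc2   # literal first half, protected second
        return [t1, t2]

    def query_tables(self, window, order):
        if GAP in window:
            raise CodeLengthError("gap queries are supported on plain code seeds only")
        c1, c2 = self.scheme.parts
        s1, s2 = tuple(window[: c1.n]), tuple(window[c1.n:])
        if order == 0:
            t1 = [c1.decode(s1) + s2]
            t2 = [s1 + c2.decode(s2)]
        elif order == 1:
            ks = comp.parallelize_keys_1mm(window)
            t1, t2 = ks.tables
        else:
            raise ValueError("composite schemes support mismatch orders 0-1")
        k1 = sorted((c1.short_code(k[: c1.n]) << (2 * c2.n)) | _pack_literal(k[c1.n:]) for k in t1)
        k2 = sorted((_pack_literal(k[: c1.n]) << (2 * c2.k)) | c2.short_code(k[c1.n:]) for k in t2)
        return [k1, k2]


class _PadLayout(_Layout):
    def storage_keys(self, wins):
        code = self.scheme.parts[0]
        sc = code.bulk_short_codes(wins[:, : code.n])
        lit = _pack_cols(wins[:, code.n:])
        return [(sc << (2 * self.scheme.pad_length)) | lit]

    def _key_int(self, key: Word) -> int:
        code = self.scheme.parts[0]
        return (code.short_code(key[: code.n]) << (2 * self.scheme.pad_length)) | _pack_literal(key[code.n:])

    def query_tables(self, window, order):
        if GAP in window:
            raise CodeLengthError("gap queries are supported on plain code seeds only")
        if order == 0:
            keys = [comp.pad_key(self.scheme, window)]
        elif order == 1:
            keys = comp.pad_keys_1mm(self.scheme, window).tables[0]
        else:
            raise ValueError("composite schemes support mismatch orders 0-1")
        return [sorted(self._key_int(k) for k in keys)]


def _make_layout(n: int | None, scheme: str, pad_length: int) -> _Layout:
    if scheme == "plain":
        return _PlainLayout(None, build_phc(n))
    if scheme == "pad":
        s = comp.CompositeScheme(kind="pad", parts=(build_phc(n),), pad_length=pad_length)
        return _PadLayout(s, None)
    if scheme in ("serialize", "parallelize"):
        s = comp.scheme_5_5(scheme)
        cls = _SerializeLayout if scheme == "serialize" else _ParallelizeLayout
        return cls(s, None)
    raise ValueError(f"unknown scheme {scheme!r}")


# ---------------------------------------------------------------------------
# The index
# ---------------------------------------------------------------------------

@dataclass
class PhcIndex:
    """Short-code-keyed position index over a genome.

    ``tables`` maps integer keys to position lists (one dict per hash
    table; parallelization uses two).  The genome text is retained so that
    candidate verification and stand-alone mapping need no second input.
    """

    layout: _Layout
    tables: list[dict[int, list[GenomePosition]]]
    sequences: dict[str, str]
    stride: int = 1
    genome_name: str = ""
    skipped_windows: int = 0

    @property
    def seed_length(self) -> int:
        return self.layout.seed_length

    @property
    def scheme(self) -> str:
        return self.layout.scheme.kind if self.layout.scheme else "plain"

    @property
    def total_positions(self) -> int:
        return sum(len(v) for v in self.tables[0].values())

    @property
    def distinct_keys(self) -> int:
        return len(self.tables[0])

    def occupancy(self) -> float:
        """Fraction of the 4ᵏ key space in use (table-density report)."""
        if self.scheme == "plain":
            space = 4 ** self.layout.code.k
        elif self.scheme == "serialize":
            space = 4 ** sum(c.k for c in self.layout.scheme.parts)
        else:
            c = self.layout.scheme.parts[0]
            lit = (
                self.layout.scheme.pad_length if self.scheme == "pad"
                else self.layout.scheme.parts[1].n
            )
            space = 4 ** (c.k + lit)
        return self.distinct_keys / space

    def window_symbols(self, pos: GenomePosition) -> Word:
        seq = self.sequences[pos.seq_id]
        return tuple(dna_to_word(seq[pos.offset: pos.offset + self.seed_length]))


def build_index(
    genome: Iterable[tuple[str, str]],
    n: int = 5,
    scheme: str = "plain",
    stride: int = 1,
    pad_length: int = 0,
    genome_name: str = "",
) -> PhcIndex:
    """Index every stride-spaced ACGT-only window of the genome, once each.

    Windows containing any other character (N etc.) are counted and skipped.
    Deterministic: positions are stored in scan order.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    layout = _make_layout(n, scheme, pad_length)
    L = layout.seed_length
    tables: list[dict[int, list[GenomePosition]]] = [dict() for _ in range(layout.n_tables)]
    sequences: dict[str, str] = {}
    skipped = 0
    any_seq = False
    for seq_id, seq in genome:
        seq_id = seq_id.split()[0]
        sequences[seq_id] = seq
        if len(seq) < L:
            continue
        any_seq = True
        arr = seq_to_symbols(seq)
        wins = np.lib.stride_tricks.sliding_window_view(arr, L)[::stride]
        offsets = np.arange(len(wins)) * stride
        good = ~(wins < 0).any(axis=1)
        skipped += int((~good).sum())
        wins, offsets = np.ascontiguousarray(wins[good]), offsets[good]
        if not len(wins):
            continue
        for table, keys in zip(tables, layout.storage_keys(wins)):
            for off, key in zip(offsets.tolist(), keys.tolist()):
                table.setdefault(key, []).append(GenomePosition(seq_id, off))
    if not sequences:
        raise ValueError("empty genome")
    if not any_seq:
        raise ValueError(f"no sequence is at least the seed length ({L}) long")
    return PhcIndex(layout=layout, tables=tables, sequences=sequences,
                    stride=stride, genome_name=genome_name, skipped_windows=skipped)


def _as_window(window, length: int) -> Word:
    if isinstance(window, str):
        window = parse_gapped(window)
    window = tuple(window)
    if len(window) != length:
        raise CodeLengthError(f"window length {len(window)} != seed length {length}")
    return window


def _verify(index: PhcIndex, window: Word, pos: GenomePosition) -> int:
    genome_win = index.window_symbols(pos)
    return sum(q != g for q, g in zip(window, genome_win) if q != GAP)


def query(
    index: PhcIndex,
    window,
    order: int = 0,
    read_id: str = "",
    strand: str = "+",
    with_byproducts: bool = False,
) -> tuple[list[Hit], LookupStats]:
    """Key-set lookup + verification for one seed window.

    ``window`` may be a DNA string (with '-' for gap slots), or a symbol
    tuple.  For gapped windows ``order`` is ignored (a gap query matches
    when the genome window equals some gap substitution).  Returns verified
    hits (distance ≤ order, or gap-distance 0) and, when requested,
    by-product candidates at greater distance as extra Hits flagged
    ``byproduct=True``.
    """
    window = _as_window(window, index.seed_length)
    gapped = GAP in window
    stats = LookupStats(reads_processed=1)
    if gapped:
        stats.baseline_lookups = 4 ** len(gap_positions(window))
    else:
        stats.baseline_lookups = neighborhood_size(index.seed_length, order)
    hits: list[Hit] = []
    byproducts: list[Hit] = []
    seen: set[GenomePosition] = set()
    for table, keys in zip(index.tables, index.layout.query_tables(window, order)):
        stats.phc_lookups += len(keys)
        for key in keys:
            for pos in table.get(key, ()):
                stats.candidates_scanned += 1
                if pos in seen:
                    continue
                seen.add(pos)
                d = _verify(index, window, pos)
                ok = (d == 0) if gapped else (d <= order)
                if ok:
                    hits.append(Hit(GenomePosition(pos.seq_id, pos.offset, strand), d, read_id))
                elif with_byproducts:
                    byproducts.append(Hit(GenomePosition(pos.seq_id, pos.offset, strand), d, read_id, True))
    stats.hits_returned = len(hits)
    hits.sort(key=lambda h: (h.position.seq_id, h.position.offset))
    if with_byproducts:
        byproducts.sort(key=lambda h: (h.position.seq_id, h.position.offset))
        return hits + byproducts, stats
    return hits, stats


# ---------------------------------------------------------------------------
# Plain-table baseline (direct neighbourhood enumeration; the oracle)
# ---------------------------------------------------------------------------

@dataclass
class PlainIndex:
    """Identity-keyed window index (the classical hash-table mapper)."""

    seed_length: int
    table: dict[int, list[GenomePosition]]
    sequences: dict[str, str]


def build_plain_index(genome: Iterable[tuple[str, str]], seed_length: int, stride: int = 1) -> PlainIndex:
    table: dict[int, list[GenomePosition]] = {}
    sequences: dict[str, str] = {}
    for seq_id, seq in genome:
        seq_id = seq_id.split()[0]
        sequences[seq_id] = seq
        if len(seq) < seed_length:
            continue
        arr = seq_to_symbols(seq)
        wins = np.lib.stride_tricks.sliding_window_view(arr, seed_length)[::stride]
        offsets = np.arange(len(wins)) * stride
        good = ~(wins < 0).any(axis=1)
        keys = _pack_cols(np.ascontiguousarray(wins[good]))
        for off, key in zip(offsets[good].tolist(), keys.tolist()):
            table.setdefault(key, []).append(GenomePosition(seq_id, off))
    return PlainIndex(seed_length=seed_length, table=table, sequences=sequences)


def baseline_query(
    index: PlainIndex, window, order: int = 0, read_id: str = "", strand: str = "+"
) -> tuple[list[Hit], LookupStats]:
    """One hash reference per neighbourhood word (or gap substitution)."""
    window = _as_window(window, index.seed_length)
    stats = LookupStats(reads_processed=1)
    if GAP in window:
        probe = {tuple(w): 0 for w in gap_substitutions(window)}
    else:
        probe = {w: hamming(w, window) for w in neighborhood(window, order)}
    hits = []
    for w, d in probe.items():
        stats.phc_lookups += 1  # references made by this (baseline) method
        for pos in index.table.get(_pack_literal(w), ()):
            stats.candidates_scanned += 1
            hits.append(Hit(GenomePosition(pos.seq_id, pos.offset, strand), d, read_id))
    stats.baseline_lookups = stats.phc_lookups
    stats.hits_returned = len(hits)
    hits.sort(key=lambda h: (h.position.seq_id, h.position.offset))
    return hits, stats


# ---------------------------------------------------------------------------
# Read mapping
# ---------------------------------------------------------------------------

def map_reads(
    index: PhcIndex,
    reads: Iterable[tuple[str, str]],
    order: int = 0,
    strand_mode: str = "forward",
    with_byproducts: bool = False,
) -> tuple[list[Hit], LookupStats]:
    """Seed-map a read set through the index.

    Each read contributes its offset-0 window only (no extension).  With
    ``strand_mode='both'`` the reverse-complemented window is also queried
    and its hits carry strand '−'.  Reads whose window leaves the symbol
    domain (unexpected characters) are counted as skipped.
    """
    if strand_mode not in ("forward", "both"):
        raise ValueError("strand_mode must be 'forward' or 'both'")
    L = index.seed_length
    agg = LookupStats()
    all_hits: list[Hit] = []
    n_reads = 0
    for read_id, seq in reads:
        n_reads += 1
        if len(seq) < L:
            agg.reads_skipped += 1
            continue
        try:
            window = parse_gapped(seq[:L])
        except SymbolDomainError:
            agg.reads_skipped += 1
            continue
        hits, stats = query(index, window, order, read_id, "+", with_byproducts)
        all_hits.extend(hits)
        agg += stats
        if strand_mode == "both":
            hits_rc, stats_rc = query(index, revcomp(window), order, read_id, "-", with_byproducts)
            all_hits.extend(hits_rc)
            agg.phc_lookups += stats_rc.phc_lookups
            agg.baseline_lookups += stats_rc.baseline_lookups
            agg.candidates_scanned += stats_rc.candidates_scanned
            agg.hits_returned += stats_rc.hits_returned
    if n_reads == 0:
        raise ValueError("empty read set")
    return all_hits, agg


# ---------------------------------------------------------------------------
# Index persistence (versioned TSV container)
# ---------------------------------------------------------------------------

_MAGIC = "#phcmap-index\tv1"


def save_index(index: PhcIndex, handle) -> None:
    """Write the index as a TSV container (text; sequences included)."""
    close = False
    if isinstance(handle, str):
        handle, close = open(handle, "w"), True
    try:
        w = handle.write
        w(_MAGIC + "\n")
        code_n = index.layout.code.n if index.layout.code else index.layout.scheme.parts[0].n
        for k, v in (
            ("scheme", index.scheme), ("n", code_n),
            ("pad_length", index.layout.scheme.pad_length if index.layout.scheme else 0),
            ("stride", index.stride), ("genome_name", index.genome_name),
            ("skipped_windows", index.skipped_windows),
        ):
            w(f"#meta\t{k}\t{v}\n")
        for seq_id, seq in index.sequences.items():
            w(f"#seq\t{seq_id}\t{seq}\n")
        for t, table in enumerate(index.tables):
            w(f"#table\t{t}\n")
            for key in sorted(table):
                for pos in table[key]:
                    w(f"{key}\t{pos.seq_id}\t{pos.offset}\n")
    finally:
        if close:
            handle.close()


def load_index(handle) -> PhcIndex:
    close = False
    if isinstance(handle, str):
        handle, close = open(handle), True
    try:
        first = handle.readline().rstrip("\n")
        if first != _MAGIC:
            raise ValueError("not a phcmap index file (bad magic line)")
        meta: dict[str, str] = {}
        sequences: dict[str, str] = {}
        tables: list[dict[int, list[GenomePosition]]] = []
        current: dict[int, list[GenomePosition]] | None = None
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "#meta":
                meta[parts[1]] = parts[2]
            elif parts[0] == "#seq":
                sequences[parts[1]] = parts[2]
            elif parts[0] == "#table":
                current = {}
                tables.append(current)
            else:
                key, seq_id, off = int(parts[0]), parts[1], int(parts[2])
                current.setdefault(key, []).append(GenomePosition(seq_id, off))
        layout = _make_layout(int(meta["n"]), meta["scheme"], int(meta["pad_length"]))
        return PhcIndex(
            layout=layout, tables=tables, sequences=sequences,
            stride=int(meta["stride"]), genome_name=meta.get("genome_name", ""),
            skipped_windows=int(meta["skipped_windows"]),
        )
    finally:
        if close:
            handle.close()
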