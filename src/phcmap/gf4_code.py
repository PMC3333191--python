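"""Arithmetic on GF(2²), DNA↔symbol mapping, and 4-ary perfect Hamming codes.

DNA k-mers are treated as words over the four-element field GF(4) =
{0, 1, α, α²} under the correspondence A↔0, C↔1, G↔α, T↔α².  Symbols are
encoded as the integers {0, 1, 2, 3} (α↦2, α²↦3); with this encoding field
addition is bitwise XOR of the two-bit values, and multiplication is a
16-entry lookup table — both small enough to stay in cache.

A q-ary (n, k) Hamming code is *perfect* when n = (q^(n-k) − 1)/(q − 1), i.e.
the radius-1 Hamming balls around the code words exactly tile the whole word
space.  Over GF(4) this holds for (n, k) = (5, 3) and (21, 18).  Decoding a
word to its unique code word at distance ≤ 1 therefore partitions all 4ⁿ
words into 4ᵏ equivalence classes of size 3n + 1, and the class centre (or
its k information digits, the *short code*) serves as a hash key that covers
the whole class with a single table reference.

Positions are 0-based everywhere in this API; user-facing text (CLI, docs)
uses the 1-based convention of the coding-theory literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product
from typing import Iterator, Sequence

import numpy as np

Word = tuple[int, ...]

#: DNA alphabet in symbol order: symbol value i encodes BASES[i].
BASES = "ACGT"
_BASE_TO_SYM = {b: i for i, b in enumerate(BASES)}
_BASE_TO_SYM.update({b.lower(): i for i, b in enumerate(BASES)})

#: Human-readable names of the field elements, indexed by encoding.
SYMBOL_NAMES = ("0", "1", "a", "a2")

# GF(4) multiplication table; addition is XOR (characteristic 2, and the
# chosen encoding makes the additive group the Klein four-group on 2 bits).
_MUL = (
    (0, 0, 0, 0),
    (0, 1, 2, 3),
    (0, 2, 3, 1),
    (0, 3, 1, 2),
)
_INV = (None, 1, 3, 2)  # multiplicative inverses of the nonzero elements


class SymbolDomainError(ValueError):
    """A character outside A/C/G/T (e.g. N) reached the GF(4) layer."""


class CodeLengthError(ValueError):
    """Word length incompatible with the active code."""


class NotACodeWordError(ValueError):
    """An operation requiring a code word received a non-code word."""


def gf4_add(a: int, b: int) -> int:
    """Field addition (= subtraction) on GF(4); XOR of the 2-bit encodings."""
    return a ^ b


def gf4_mul(a: int, b: int) -> int:
    """Field multiplication on GF(4)."""
    return _MUL[a][b]


def gf4_inv(a: int) -> int:
    """Multiplicative inverse of a nonzero element."""
    if a == 0:
        raise ZeroDivisionError("0 has no multiplicative inverse in GF(4)")
    return _INV[a]


def dna_to_word(seq: str) -> Word:
    """Map a DNA string to a GF(4) word (A→0, C→1, G→α, T→α²).

    Case-insensitive; any character outside ACGT (including N) raises
    :class:`SymbolDomainError` — ambiguity handling belongs to the index
    layer, not the symbol domain.
    """
    try:
        return tuple(_BASE_TO_SYM[b] for b in seq)
    except KeyError as exc:
        raise SymbolDomainError(
            f"character {exc.args[0]!r} is not in the DNA alphabet ACGT"
        ) from None


def word_to_dna(word: Sequence[int]) -> str:
    """Inverse of :func:`dna_to_word`."""
    return "".join(BASES[s] for s in word)


def hamming(u: Sequence[int], v: Sequence[int]) -> int:
    """Hamming distance between two equal-length words."""
    if len(u) != len(v):
        raise CodeLengthError(f"length mismatch: {len(u)} vs {len(v)}")
    return sum(a != b for a, b in zip(u, v))


def all_words(n: int) -> Iterator[Word]:
    """All 4ⁿ GF(4) words of length n, lexicographically."""
    return product(range(4), repeat=n)


# ---------------------------------------------------------------------------
# GF(4) linear algebra (small dense matrices, used only at code construction)
# ---------------------------------------------------------------------------

def _mat_vec(m: Sequence[Sequence[int]], v: Sequence[int]) -> tuple[int, ...]:
    out = []
    for row in m:
        acc = 0
        for a, b in zip(row, v):
            acc ^= _MUL[a][b]
        out.append(acc)
    return tuple(out)


def _mat_inv(m: Sequence[Sequence[int]]) -> list[list[int]] | None:
    """Inverse of a square GF(4) matrix by Gauss–Jordan; None if singular."""
    r = len(m)
    aug = [list(row) + [int(i == j) for j in range(r)] for i, row in enumerate(m)]
    for col in range(r):
        piv = next((i for i in range(col, r) if aug[i][col] != 0), None)
        if piv is None:
            return None
        aug[col], aug[piv] = aug[piv], aug[col]
        inv = _INV[aug[col][col]]
        aug[col] = [_MUL[inv][x] for x in aug[col]]
        for i in range(r):
            if i != col and aug[i][col] != 0:
                f = aug[i][col]
                aug[i] = [x ^ _MUL[f][y] for x, y in zip(aug[i], aug[col])]
    return [row[r:] for row in aug]


# ---------------------------------------------------------------------------
# Perfect Hamming codes
# ---------------------------------------------------------------------------

# The (5,3) parity-check matrix, frozen: columns (1,1), (0,1), (1,0), (1,α),
# (1,α²).  This is the assignment consistent with all published worked
# decodings of the code (e.g. AAAAG→AAAAA, CAAAT→CAAGT, ACACA→ACACC); the
# order of the two unit columns is a documented convention.
_H5 = (
    (1, 0, 1, 1, 1),
    (1, 1, 0, 2, 3),
)
_H5_CHECK = (1, 2)  # positions 2,3 in 1-based terms; the unit-column pair


def _h21_columns() -> list[tuple[int, int, int]]:
    """The 21 projective points of GF(4)³: normalised (first nonzero entry 1)
    representatives, in lexicographic order of the encoded triples."""
    cols: set[tuple[int, int, int]] = set()
    for v in product(range(4), repeat=3):
        if v == (0, 0, 0):
            continue
        lead = next(x for x in v if x != 0)
        inv = _INV[lead]
        cols.add(tuple(_MUL[inv][x] for x in v))
    return sorted(cols)


@dataclass(frozen=True)
class PhcCode:
    """A 4-ary (n, k) perfect Hamming code with its decoding machinery.

    Attributes
    ----------
    n, k : int
        Code length and number of information digits; n − k check digits.
    H : tuple of rows
        The (n−k) × n parity-check matrix over GF(4).
    info_positions, check_positions : tuple of int
        0-based positions of the information digits (the short code) and the
        check digits; the check submatrix of ``H`` is invertible, so a code
        word is determined by its information digits alone.
    """

    n: int
    k: int
    H: tuple[tuple[int, ...], ...]
    info_positions: tuple[int, ...]
    check_positions: tuple[int, ...]
    # packed syndrome -> (error position, error magnitude); {} entry 0 unused
    _synd_to_error: dict[int, tuple[int, int]] = field(repr=False, hash=False, compare=False, default_factory=dict)
    # per-position, per-symbol packed syndrome contributions
    _contrib: tuple[tuple[int, ...], ...] = field(repr=False, compare=False, default=())
    # packed syndrome -> XOR mask on the packed short code (0 for check-digit errors)
    _short_fix: tuple[int, ...] = field(repr=False, compare=False, default=())
    # solver for check digits: check = _check_solver · (H_info · info)
    _check_solver: tuple[tuple[int, ...], ...] = field(repr=False, compare=False, default=())

    # -- construction -------------------------------------------------------

    @staticmethod
    def _build(n: int) -> "PhcCode":
        if n == 5:
            H = _H5
            check = _H5_CHECK
        elif n == 21:
            cols = _h21_columns()
            H = tuple(tuple(c[i] for c in cols) for i in range(3))
            # greedy left-to-right: keep columns that extend the rank
            chosen: list[int] = []
            for j in range(21):
                trial = chosen + [j]
                sub = [[H[i][p] for p in trial] for i in range(3)]
                if _gf4_rank(sub) == len(trial):
                    chosen = trial
                if len(chosen) == 3:
                    break
            check = tuple(chosen)
        else:
            raise CodeLengthError(
                f"no 4-ary perfect Hamming code of length {n}: 3l + 1 must be "
                "a power of 4 (supported lengths: 5, 21)"
            )
        r = len(H)
        k = n - r
        info = tuple(j for j in range(n) if j not in check)

        # packed syndrome contribution of symbol v at position j
        contrib = tuple(
            tuple(_pack(tuple(_MUL[H[i][j]][v] for i in range(r))) for v in range(4))
            for j in range(n)
        )
        # every nonzero syndrome is t · (column j) for exactly one (j, t)
        synd_to_error: dict[int, tuple[int, int]] = {}
        for j in range(n):
            for t in (1, 2, 3):
                s = contrib[j][t]
                assert s not in synd_to_error, "parity-check columns not pairwise independent"
                synd_to_error[s] = (j, t)
        assert len(synd_to_error) == 4**r - 1, "columns do not cover all syndromes"

        info_index = {p: i for i, p in enumerate(info)}
        short_fix = [0] * (4**r)
        for s, (j, t) in synd_to_error.items():
            if j in info_index:
                short_fix[s] = t << (2 * (k - 1 - info_index[j]))

        check_sub = [[H[i][p] for p in check] for i in range(r)]
        solver = _mat_inv(check_sub)
        assert solver is not None, "check submatrix must be invertible"

        return PhcCode(
            n=n, k=k, H=H, info_positions=info, check_positions=check,
            _synd_to_error=synd_to_error, _contrib=contrib,
            _short_fix=tuple(short_fix),
            _check_solver=tuple(tuple(row) for row in solver),
        )

    # -- syndrome decoding ---------------------------------------------------

    def _packed_syndrome(self, z: Sequence[int]) -> int:
        if len(z) != self.n:
            raise CodeLengthError(f"expected a length-{self.n} word, got {len(z)}")
        acc = 0
        for j, v in enumerate(z):
            acc ^= self._contrib[j][v]
        return acc

    def syndrome(self, z: Sequence[int]) -> tuple[int, ...]:
        """The syndrome z·Hᵀ; the zero vector exactly for code words."""
        return _unpack(self._packed_syndrome(z), self.n - self.k)

    def is_code_word(self, z: Sequence[int]) -> bool:
        return self._packed_syndrome(z) == 0

    def decode(self, z: Sequence[int]) -> Word:
        """The unique code word at Hamming distance ≤ 1 from ``z``.

        A nonzero syndrome equals a scalar multiple t of exactly one column
        of H; that column is the error position and t the error magnitude,
        which is subtracted (= XORed, characteristic 2) from the word.
        """
        s = self._packed_syndrome(z)
        if s == 0:
            return tuple(z)
        try:
            j, t = self._synd_to_error[s]
        except KeyError:  # pragma: no cover - impossible for a valid PHC
            raise AssertionError("corrupted parity-check matrix: unmatched syndrome")
        w = list(z)
        w[j] ^= t
        return tuple(w)

    # -- short codes ---------------------------------------------------------

    def short_code(self, c: Sequence[int]) -> int:
        """Pack the information digits of code word ``c`` into [0, 4ᵏ).

        The digit at the smallest information position is the most
        significant base-4 digit.  Raises :class:`NotACodeWordError` for
        non-code words (use :meth:`decode` first).
        """
        if self._packed_syndrome(c) != 0:
            raise NotACodeWordError(f"{word_to_dna(c)} is not a code word")
        acc = 0
        for p in self.info_positions:
            acc = (acc << 2) | c[p]
        return acc

    def short_code_of(self, z: Sequence[int]) -> int:
        """``short_code(decode(z))`` without materialising the code word."""
        s = self._packed_syndrome(z)
        acc = 0
        for p in self.info_positions:
            acc = (acc << 2) | z[p]
        return acc ^ self._short_fix[s]

    def from_short_code(self, sc: int) -> Word:
        """Expand a short code back to its full code word (bijection inverse)."""
        if not 0 <= sc < 4**self.k:
            raise ValueError(f"short code {sc} out of range [0, 4^{self.k})")
        info_digits = _unpack(sc, self.k)
        w = [0] * self.n
        for p, d in zip(self.info_positions, info_digits):
            w[p] = d
        rhs = _mat_vec(self.H, w)  # H_info · info  (check digits still zero)
        check_digits = _mat_vec(self._check_solver, rhs)
        for p, d in zip(self.check_positions, check_digits):
            w[p] = d
        return tuple(w)

    # -- equivalence classes -------------------------------------------------

    def equiv_class(self, c: Sequence[int]) -> set[Word]:
        """The class of centre ``c``: the code word plus its 3n distance-1
        neighbours (3n + 1 words in total)."""
        if self._packed_syndrome(c) != 0:
            raise NotACodeWordError(f"{word_to_dna(c)} is not a code word")
        c = tuple(c)
        out = {c}
        for j in range(self.n):
            for t in (1, 2, 3):
                w = list(c)
                w[j] ^= t
                out.add(tuple(w))
        return out

    def code_words(self) -> Iterator[Word]:
        """All 4ᵏ code words, in short-code order."""
        for sc in range(4**self.k):
            yield self.from_short_code(sc)

    # -- bulk (vectorised) encoding ------------------------------------------

    def bulk_short_codes(self, windows: np.ndarray) -> np.ndarray:
        """Short codes of ``decode(row)`` for every row of an (m, n) symbol array.

        Rows are symbol-encoded windows (values 0–3).  Syndromes, error
        corrections and information-digit packing are all table lookups, so
        the whole pipeline is vectorised; used by the genome indexer.
        """
        if windows.ndim != 2 or windows.shape[1] != self.n:
            raise CodeLengthError(f"expected an (m, {self.n}) array")
        contrib = np.asarray(self._contrib, dtype=np.int64)  # (n, 4)
        synd = np.zeros(len(windows), dtype=np.int64)
        for j in range(self.n):
            synd ^= contrib[j][windows[:, j]]
        packed = np.zeros(len(windows), dtype=np.int64)
        for p in self.info_positions:
            packed = (packed << 2) | windows[:, p].astype(np.int64)
        return packed ^ np.asarray(self._short_fix, dtype=np.int64)[synd]


def _pack(digits: Sequence[int]) -> int:
    acc = 0
    for d in digits:
        acc = (acc << 2) | d
    return acc


def _unpack(value: int, length: int) -> tuple[int, ...]:
    return tuple((value >> (2 * (length - 1 - i))) & 3 for i in range(length))


def _gf4_rank(m: Sequence[Sequence[int]]) -> int:
    rows = [list(r) for r in m]
    ncols = len(rows[0]) if rows else 0
    rank = 0
    for col in range(ncols):
        piv = next((i for i in range(rank, len(rows)) if rows[i][col] != 0), None)
        if piv is None:
            continue
        rows[rank], rows[piv] = rows[piv], rows[rank]
        inv = _INV[rows[rank][col]]
        rows[rank] = [_MUL[inv][x] for x in rows[rank]]
        for i in range(len(rows)):
            if i != rank and rows[i][col] != 0:
                f = rows[i][col]
                rows[i] = [x ^ _MUL[f][y] for x, y in zip(rows[i], rows[rank])]
        rank += 1
    return rank


@lru_cache(maxsize=None)
def build_phc(n: int) -> PhcCode:
    """The 4-ary perfect Hamming code of length n ∈ {5, 21} (cached)."""
    return PhcCode._build(n)


# Thin functional aliases over the PhcCode methods.

def syndrome(code: PhcCode, z: Sequence[int]) -> tuple[int, ...]:
    return code.syndrome(z)


def decode(code: PhcCode, z: Sequence[int]) -> Word:
    return code.decode(z)


def short_code(code: PhcCode, c: Sequence[int]) -> int:
    return code.short_code(c)


def equiv_class(code: PhcCode, c: Sequence[int]) -> set[Word]:
    return code.equiv_class(c)


def kmer_code_table(n: int = 5) -> Iterator[tuple[str, str, int]]:
    """(kmer, code_word_kmer, short_code_int) for every length-n k-mer.

    Regenerates the full 5-mer ↔ code-word correspondence table (4ⁿ rows;
    each of the 4ᵏ code words appears exactly 3n + 1 times as a centre).
    """
    code = build_phc(n)
    for w in all_words(n):
        c = code.decode(w)
        yield word_to_dna(w), word_to_dna(c), code.short_code(c)
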