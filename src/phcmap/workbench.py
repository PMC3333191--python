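"""Synthetic genomes and read sets, plus FASTA/FASTQ plumbing.

Everything the mapper and its tests consume can be generated here from a
seed, so no download or binary fixture is ever needed.  Reads are sampled
from recorded genome positions with a chosen number of planted mismatches
or gap slots inside the seed window, and every simulated read set ships
with a truth table for plant-and-recover checks.

A single seeded NumPy generator drives each invocation; identical spec +
seed gives byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .keysets import GAP_CHAR

log = logging.getLogger("phcmap")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a simulated mapping instance.

    Defaults emulate a small bacterial-scale test locus read by an early
    short-read instrument: a 10 kb i.i.d. genome at human-like 41% GC,
    1000 reads of 36 bp sampled uniformly, edits planted inside the seed
    window so that seed-level recovery is decidable from the truth table.
    """

    genome_length: int = 10_000
    gc_fraction: float = 0.41
    n_reads: int = 1000
    read_length: int = 36
    seed_window: int = 5          # edits are planted within the first seed_window bases
    planted_mismatches: int = 0
    planted_gaps: int = 0
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        if self.genome_length < self.seed_window:
            raise ValueError("genome shorter than the seed window")
        if self.read_length > self.genome_length:
            raise ValueError("read_length exceeds genome length")
        if self.planted_mismatches + self.planted_gaps > self.seed_window:
            raise ValueError("more planted edits than seed-window positions")


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    seq_id: str
    offset: int
    strand: str
    edits: str  # e.g. "mismatch:2;gap:4" (0-based window positions)


def generate_genome(spec: SyntheticSpec) -> list[tuple[str, str]]:
    """One i.i.d. sequence at the requested GC fraction; deterministic."""
    rng = np.random.default_rng(spec.rng_seed)
    p_gc = spec.gc_fraction / 2
    p_at = (1.0 - spec.gc_fraction) / 2
    probs = (p_at, p_gc, p_gc, p_at)  # A, C, G, T
    draw = rng.choice(4, size=spec.genome_length, p=probs)
    seq = _BASES[draw].tobytes().decode("ascii")
    return [("synth1", seq)]


def generate_reads(
    genome: list[tuple[str, str]], spec: SyntheticSpec
) -> tuple[list[tuple[str, str]], list[TruthRecord]]:
    """Sample reads from recorded positions and plant the requested edits.

    Mismatches substitute a different base; gap plants write the '-' gap
    symbol (an unknown base to be matched by gap query).  All edits land at
    distinct positions inside the first ``seed_window`` bases, so the truth
    offset is recoverable by a seed query of the matching order.
    """
    rng = np.random.default_rng(spec.rng_seed + 1)
    seq_id, seq = genome[0]
    max_start = len(seq) - spec.read_length
    reads: list[tuple[str, str]] = []
    truth: list[TruthRecord] = []
    n_edits = spec.planted_mismatches + spec.planted_gaps
    for i in range(spec.n_reads):
        start = int(rng.integers(0, max_start + 1))
        read = list(seq[start: start + spec.read_length])
        positions = rng.permutation(spec.seed_window)[:n_edits]
        edits = []
        for j, p in enumerate(positions.tolist()):
            if j < spec.planted_mismatches:
                old = read[p]
                choices = [b for b in "ACGT" if b != old]
                read[p] = choices[int(rng.integers(3))]
                edits.append(f"mismatch:{p}")
            else:
                read[p] = GAP_CHAR
                edits.append(f"gap:{p}")
        rid = f"read{i:05d}"
        reads.append((rid, "".join(read)))
        truth.append(TruthRecord(rid, seq_id, start, "+", ";".join(sorted(edits)) or "none"))
    return reads, truth


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def write_fasta(records: Iterable[tuple[str, str]], path: str) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records),
        path, "fasta",
    )


def read_fasta(path: str) -> Iterator[tuple[str, str]]:
    for rec in SeqIO.parse(path, "fasta"):
        yield rec.id, str(rec.seq)


def write_fastq(records: Iterable[tuple[str, str]], path: str, quality: int = 30) -> None:
    """Sanger FASTQ with a constant quality score (qualities carry no signal
    in this pipeline and are ignored on input)."""
    def _recs():
        for rid, seq in records:
            r = SeqRecord(Seq(seq), id=rid, description="")
            r.letter_annotations["phred_quality"] = [quality] * len(seq)
            yield r
    SeqIO.write(_recs(), path, "fastq")


def read_sequences(path: str) -> Iterator[tuple[str, str]]:
    """FASTA or FASTQ, sniffed from the first character."""
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    for rec in SeqIO.parse(path, fmt):
        yield rec.id, str(rec.seq)


def write_truth_tsv(truth: Iterable[TruthRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tseq_id\toffset\tstrand\tedits\n")
        for t in truth:
            fh.write(f"{t.read_id}\t{t.seq_id}\t{t.offset}\t{t.strand}\t{t.edits}\n")


def read_truth_tsv(path: str) -> list[TruthRecord]:
    out = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            rid, sid, off, strand, edits = line.rstrip("\n").split("\t")
            out.append(TruthRecord(rid, sid, int(off), strand, edits))
    return out
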