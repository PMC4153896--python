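"""Circular genome representation and circle arithmetic.

Mitochondrial genomes are circular; every coordinate in this package is
1-based and taken modulo the genome length ``L``, so position ``p`` and
``p + L`` name the same base.  Midpoints of even-length elements are exact
half-integers (e.g. 57.5), never rounded inside computations — rounding to
integers happens only in human-readable reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class GenomeError(ValueError):
    """Raised for malformed genome input (bad FASTA, illegal characters)."""


@dataclass(frozen=True)
class CircularGenome:
    """An immutable circular nucleotide sequence.

    Parameters
    ----------
    id : str
        Record identifier (FASTA header up to the first whitespace).
    sequence : str
        Bases over ``{A, C, G, T, N}``; stored uppercased.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if len(seq) < 1:
            raise GenomeError("genome sequence must contain at least one base")
        bad = set(seq) - _ALPHABET
        if bad:
            raise GenomeError(
                f"illegal characters in genome {self.id!r}: {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, length: int) -> str:
        """Circular substring of ``length`` bases starting at 1-based ``start``."""
        if length < 0:
            raise ValueError("length must be non-negative")
        L = len(self.sequence)
        i = (int(start) - 1) % L
        doubled = self.sequence + self.sequence
        if length > L:
            reps = (i + length) // L + 1
            doubled = self.sequence * reps
        return doubled[i : i + length]

    def base_composition(self) -> dict[str, int]:
        return {b: self.sequence.count(b) for b in "ACGTN"}

    def strand_g_content(self) -> dict[str, float]:
        """Fraction of G on the deposited (reference) strand and its complement."""
        comp = self.base_composition()
        L = len(self.sequence)
        return {"reference": comp["G"] / L, "complement": comp["C"] / L}

    @property
    def heavy_strand(self) -> str:
        """The G-richer strand, by convention the 'heavy' strand of mtDNA."""
        g = self.strand_g_content()
        return "reference" if g["reference"] >= g["complement"] else "complement"


def read_fasta(path: str | Path) -> CircularGenome:
    """Read a single-record FASTA file as a circular genome.

    Raises :class:`GenomeError` for empty files, multiple records,
    zero-length sequences or characters outside ``{A,C,G,T,N}``.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise GenomeError(f"{path}: no FASTA records found")
    if len(records) > 1:
        raise GenomeError(f"{path}: expected exactly one record, found {len(records)}")
    rec = records[0]
    seq = str(rec.seq)
    if len(seq) == 0:
        raise GenomeError(f"{path}: record {rec.id!r} has zero-length sequence")
    return CircularGenome(id=rec.id, sequence=seq)


def write_fasta(genome: CircularGenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, len(genome.sequence), width):
            fh.write(genome.sequence[i : i + width] + "\n")


def write_genome_metadata(genome: CircularGenome, path: str | Path) -> None:
    """TSV export of genome id, length and base composition."""
    comp = genome.base_composition()
    with open(path, "w") as fh:
        fh.write("id\tlength\t" + "\t".join(comp) + "\n")
        fh.write(
            f"{genome.id}\t{len(genome)}\t" + "\t".join(str(v) for v in comp.values()) + "\n"
        )


def reverse_complement(seq: str) -> str:
    """Reverse complement over ``{A,C,G,T,N}`` (N maps to N)."""
    bad = set(seq.upper()) - _ALPHABET
    if bad:
        raise GenomeError(f"illegal characters in sequence: {sorted(bad)}")
    return seq.upper().translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    """Base-wise complement without reversal."""
    bad = set(seq.upper()) - _ALPHABET
    if bad:
        raise GenomeError(f"illegal characters in sequence: {sorted(bad)}")
    return seq.upper().translate(_COMPLEMENT)


def canonical_position(p: float, L: int) -> float:
    """Map a (possibly fractional) position onto the canonical range [1, L+1)."""
    return ((p - 1.0) % L) + 1.0


def circular_distance(a: float, b: float, L: int) -> float:
    """Minimal distance between two positions on a circle of length L.

    Always in ``[0, L/2]``; direction-agnostic (the shorter of the clockwise
    and counter-clockwise walks).
    """
    d = abs(a - b) % L
    return min(d, L - d)


def rotate_positions(points: Iterable[float], r: int, L: int) -> list[float]:
    """Rotate every position by ``r`` nucleotides around a circle of length L.

    Fractional parts (half-integer midpoints) are preserved.
    """
    return [((p - 1.0 + r) % L) + 1.0 for p in points]


def positions_to_half_units(points: Sequence[float], L: int) -> np.ndarray:
    """Map 1-based positions (integers or half-integers) to integer indices on
    the doubled half-unit grid ``0 .. 2L-1`` (position p -> round(2(p-1)) mod 2L)."""
    arr = np.asarray(list(points), dtype=float)
    if arr.size and (np.any(arr < -1e9) or not np.all(np.isfinite(arr))):
        raise ValueError("positions must be finite")
    idx = np.rint(2.0 * (arr - 1.0)).astype(np.int64) % (2 * L)
    return idx
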