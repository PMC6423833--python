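"""Assemblies, contiguity statistics and resolution filtering.

An :class:`Assembly` is a named, ordered collection of sequence fragments
(scaffolds or contigs).  Scoring only needs fragment lengths, so sequence
content is optional: assemblies can be loaded from FASTA or from a
two-column ``id<TAB>length`` table.

The Nx statistic (N50, N90, ...) is the length-weighted median family used
throughout assembly evaluation: the length of the fragment at which
fragments sorted by decreasing length first accumulate a fraction ``x`` of
the total assembly length.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from Bio import SeqIO

from .errors import InputError

__all__ = [
    "SequenceRecord",
    "Assembly",
    "FilteredAssemblyStats",
    "read_fasta",
    "read_lengths_table",
    "nx_statistic",
    "filter_fragments",
]

# IUPAC nucleotide codes plus gap characters; used to sanity-check that a
# FASTA record is nucleotide sequence rather than protein or garbage.
_NUCLEOTIDE_CHARS = frozenset("ACGTUNRYSWKMBDHVacgtunryswkmbdhv-.")
_MIN_NUCLEOTIDE_FRACTION = 0.9


@dataclass(frozen=True)
class SequenceRecord:
    """One assembly fragment: an id, its length in bp, optional sequence."""

    id: str
    length: int
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise InputError(f"record {self.id!r}: length must be >= 1, got {self.length}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise InputError(
                f"record {self.id!r}: sequence has {len(self.sequence)} characters "
                f"but declared length is {self.length}"
            )


@dataclass
class Assembly:
    """A named set of sequence fragments with unique ids."""

    name: str
    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise InputError(f"assembly {self.name!r} has no records")
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise InputError(f"assembly {self.name!r}: duplicate fragment id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def total_length(self) -> int:
        return sum(r.length for r in self.records)

    @property
    def lengths(self) -> dict[str, int]:
        return {r.id: r.length for r in self.records}

    def record(self, fragment_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == fragment_id:
                return rec
        raise KeyError(fragment_id)


@dataclass(frozen=True)
class FilteredAssemblyStats:
    """Count and total length of fragments strictly longer than a resolution.

    These are the c(A) and l(A) quantities of the count and length scores:
    only fragments longer than the resolution take part in CSB construction
    and in the denominators of the per-resolution scores.
    """

    resolution_bp: int
    fragment_count: int
    total_length_bp: int

    def __post_init__(self) -> None:
        if self.fragment_count > 0 and self.total_length_bp < self.fragment_count * self.resolution_bp:
            raise InputError(
                "inconsistent filtered stats: total length "
                f"{self.total_length_bp} < {self.fragment_count} fragments x "
                f"resolution {self.resolution_bp}"
            )
        if (self.fragment_count == 0) != (self.total_length_bp == 0):
            raise InputError("fragment_count and total_length_bp must be zero together")


def _open_text(path: Union[str, Path]):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: Union[str, Path], name: Optional[str] = None, keep_sequences: bool = True) -> Assembly:
    """Read an assembly from a (possibly gzipped) FASTA file.

    Fragment ids are the FASTA headers up to the first whitespace; lengths
    count every sequence character regardless of case (soft-masked and N
    bases included).  Records whose content is not dominated by nucleotide
    codes are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA file not found: {path}")
    records: list[SequenceRecord] = []
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq)
            if not seq:
                raise InputError(f"{path}: record {rec.id!r} has empty sequence")
            nuc = sum(1 for ch in seq if ch in _NUCLEOTIDE_CHARS)
            if nuc / len(seq) < _MIN_NUCLEOTIDE_FRACTION:
                raise InputError(
                    f"{path}: record {rec.id!r} does not look like nucleotide sequence"
                )
            records.append(
                SequenceRecord(rec.id, len(seq), seq if keep_sequences else None)
            )
    if not records:
        raise InputError(f"{path}: no FASTA records found")
    return Assembly(name if name is not None else path.stem, records)


def read_lengths_table(path: Union[str, Path], name: Optional[str] = None) -> Assembly:
    """Read a lengths-only assembly from a two-column ``id<TAB>length`` table.

    Such tables come from ``samtools faidx`` output or ``seqkit fx2tab``;
    they are enough for scoring, which never touches sequence content.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"lengths table not found: {path}")
    records: list[SequenceRecord] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InputError(f"{path}:{lineno}: expected 'id<TAB>length'")
            try:
                length = int(parts[1])
            except ValueError:
                raise InputError(f"{path}:{lineno}: length {parts[1]!r} is not an integer")
            records.append(SequenceRecord(parts[0], length))
    if not records:
        raise InputError(f"{path}: no rows found")
    return Assembly(name if name is not None else path.stem, records)


def _sorted_lengths(assembly: Assembly) -> list[int]:
    # descending length, ties broken by id so output is deterministic
    return [r.length for r in sorted(assembly.records, key=lambda r: (-r.length, r.id))]


def nx_statistic(assembly: Assembly, x: float) -> int:
    """Return the Nx value of an assembly (N50 is ``x=0.5``, N90 ``x=0.9``).

    Scanning fragments sorted by decreasing length, Nx is the length of the
    first fragment at which the cumulative length reaches ``x`` times the
    total assembly length.
    """
    if not 0.0 < x <= 1.0:
        raise ValueError(f"x must be in (0, 1], got {x}")
    lengths = _sorted_lengths(assembly)
    threshold = x * sum(lengths)
    cumulative = 0
    for length in lengths:
        cumulative += length
        if cumulative >= threshold or math.isclose(cumulative, threshold):
            return length
    return lengths[-1]  # unreachable: cumulative ends at the total


def filter_fragments(assembly: Assembly, resolution_bp: int) -> FilteredAssemblyStats:
    """Count and sum fragments strictly longer than ``resolution_bp``.

    The strict inequality follows the definition of the filtered quantities
    l(A) and c(A): a fragment exactly as long as the resolution cannot hold
    a CSB longer than itself and is excluded.
    """
    if resolution_bp < 1:
        raise ValueError(f"resolution_bp must be >= 1, got {resolution_bp}")
    survivors = [r.length for r in assembly.records if r.length > resolution_bp]
    return FilteredAssemblyStats(
        resolution_bp=resolution_bp,
        fragment_count=len(survivors),
        total_length_bp=sum(survivors),
    )
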