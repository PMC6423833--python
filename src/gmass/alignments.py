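"""Pairwise local-alignment fragments between two assemblies.

Fragments are stored in the PAF convention: 0-based half-open intervals,
with the query interval always on the forward strand and a ``strand`` flag
recording the orientation of the query relative to the reference.  PAF is
read and written directly; MAF blocks (two sequences per block, reference
first) are converted to the same convention on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from Bio import AlignIO

from .assembly import Assembly
from .errors import InputError

__all__ = [
    "AlignmentFragment",
    "AlignmentSet",
    "read_paf",
    "write_paf",
    "read_maf",
]


@dataclass(frozen=True)
class AlignmentFragment:
    """One local alignment between a reference and a query interval.

    ``score`` is the number of matched bases when the source format provides
    it, otherwise the alignment length; it is used only to prioritise
    fragments during overlap resolution.
    """

    ref_id: str
    ref_start: int
    ref_end: int
    query_id: str
    query_start: int
    query_end: int
    strand: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.ref_start < 0 or self.ref_start >= self.ref_end:
            raise InputError(
                f"invalid reference interval [{self.ref_start}, {self.ref_end}) on {self.ref_id!r}"
            )
        if self.query_start < 0 or self.query_start >= self.query_end:
            raise InputError(
                f"invalid query interval [{self.query_start}, {self.query_end}) on {self.query_id!r}"
            )
        if self.strand not in ("+", "-"):
            raise InputError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.score < 0:
            raise InputError(f"score must be non-negative, got {self.score}")

    @property
    def ref_length(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def query_length(self) -> int:
        return self.query_end - self.query_start

    def swapped(self) -> "AlignmentFragment":
        """The same alignment with reference and query roles exchanged."""
        return AlignmentFragment(
            ref_id=self.query_id,
            ref_start=self.query_start,
            ref_end=self.query_end,
            query_id=self.ref_id,
            query_start=self.ref_start,
            query_end=self.ref_end,
            strand=self.strand,
            score=self.score,
        )


@dataclass
class AlignmentSet:
    """A collection of alignment fragments between two named assemblies."""

    reference: str
    query: str
    fragments: list[AlignmentFragment] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    def swapped(self) -> "AlignmentSet":
        return AlignmentSet(
            reference=self.query,
            query=self.reference,
            fragments=[f.swapped() for f in self.fragments],
        )

    def validate_against(self, reference: Assembly, query: Assembly) -> None:
        """Check that every fragment fits inside the named assembly fragments."""
        ref_lengths = reference.lengths
        query_lengths = query.lengths
        for frag in self.fragments:
            if frag.ref_id not in ref_lengths:
                raise InputError(f"unknown reference sequence {frag.ref_id!r}")
            if frag.query_id not in query_lengths:
                raise InputError(f"unknown query sequence {frag.query_id!r}")
            if frag.ref_end > ref_lengths[frag.ref_id]:
                raise InputError(
                    f"alignment end {frag.ref_end} exceeds length "
                    f"{ref_lengths[frag.ref_id]} of reference {frag.ref_id!r}"
                )
            if frag.query_end > query_lengths[frag.query_id]:
                raise InputError(
                    f"alignment end {frag.query_end} exceeds length "
                    f"{query_lengths[frag.query_id]} of query {frag.query_id!r}"
                )


def read_paf(path: Union[str, Path], reference: Assembly, query: Assembly) -> AlignmentSet:
    """Read alignments from a PAF file (minimap2 dialect, 12+ columns).

    PAF column 6 (target) maps to the reference assembly and column 1 to the
    query.  Coordinates are kept as-is (PAF is natively 0-based half-open
    with forward-strand query coordinates); the score is column 10, the
    number of matching bases.  Optional SAM-style tags are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"PAF file not found: {path}")
    ref_lengths = reference.lengths
    query_lengths = query.lengths
    fragments: list[AlignmentFragment] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise InputError(f"{path}:{lineno}: PAF needs >= 12 columns, got {len(cols)}")
            qname, tname, strand = cols[0], cols[5], cols[4]
            try:
                qlen, qstart, qend = int(cols[1]), int(cols[2]), int(cols[3])
                tlen, tstart, tend = int(cols[6]), int(cols[7]), int(cols[8])
                matches = int(cols[9])
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: non-integer coordinate field ({exc})")
            if qname not in query_lengths:
                raise InputError(f"{path}:{lineno}: unknown query sequence {qname!r}")
            if tname not in ref_lengths:
                raise InputError(f"{path}:{lineno}: unknown target sequence {tname!r}")
            if qend > query_lengths[qname] or qend > qlen:
                raise InputError(
                    f"{path}:{lineno}: query coordinate {qend} outside {qname!r} "
                    f"(length {query_lengths[qname]})"
                )
            if tend > ref_lengths[tname] or tend > tlen:
                raise InputError(
                    f"{path}:{lineno}: target coordinate {tend} outside {tname!r} "
                    f"(length {ref_lengths[tname]})"
                )
            try:
                fragments.append(
                    AlignmentFragment(
                        ref_id=tname,
                        ref_start=tstart,
                        ref_end=tend,
                        query_id=qname,
                        query_start=qstart,
                        query_end=qend,
                        strand=strand,
                        score=matches,
                    )
                )
            except InputError as exc:
                raise InputError(f"{path}:{lineno}: {exc}")
    return AlignmentSet(reference=reference.name, query=query.name, fragments=fragments)


def write_paf(
    alignments: AlignmentSet,
    path: Union[str, Path],
    reference: Assembly,
    query: Assembly,
) -> None:
    """Write an AlignmentSet as 12-column PAF (mapping quality fixed at 255)."""
    ref_lengths = reference.lengths
    query_lengths = query.lengths
    with open(path, "w") as handle:
        for frag in alignments:
            block = max(frag.ref_length, frag.query_length)
            handle.write(
                "\t".join(
                    str(v)
                    for v in (
                        frag.query_id,
                        query_lengths[frag.query_id],
                        frag.query_start,
                        frag.query_end,
                        frag.strand,
                        frag.ref_id,
                        ref_lengths[frag.ref_id],
                        frag.ref_start,
                        frag.ref_end,
                        int(frag.score),
                        block,
                        255,
                    )
                )
                + "\n"
            )


def read_maf(path: Union[str, Path], reference: Assembly, query: Assembly) -> AlignmentSet:
    """Read alignments from a MAF file (UCSC dialect, pairwise blocks).

    Each block must contain exactly two 's' lines, reference first; blocks
    with any other number of sequences are skipped with a single summary
    warning.  MAF minus-strand coordinates (counted from the 3' end) are
    converted to forward-strand 0-based half-open intervals.  The block
    score comes from the ``a score=`` field, defaulting to the number of
    aligned columns.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"MAF file not found: {path}")
    ref_lengths = reference.lengths
    query_lengths = query.lengths
    fragments: list[AlignmentFragment] = []
    skipped = 0
    with open(path) as handle:
        for block in AlignIO.parse(handle, "maf"):
            if len(block) != 2:
                skipped += 1
                continue
            ref_row, query_row = block[0], block[1]
            if ref_row.id not in ref_lengths and query_row.id in ref_lengths:
                ref_row, query_row = query_row, ref_row
            if ref_row.id not in ref_lengths:
                raise InputError(f"{path}: unknown reference sequence {ref_row.id!r}")
            if query_row.id not in query_lengths:
                raise InputError(f"{path}: unknown query sequence {query_row.id!r}")
            if ref_row.annotations["strand"] != 1:
                raise InputError(
                    f"{path}: reference line for {ref_row.id!r} is on the minus "
                    "strand; MAF blocks must be reference-forward"
                )
            ref_start = int(ref_row.annotations["start"])
            ref_end = ref_start + int(ref_row.annotations["size"])
            qstart_native = int(query_row.annotations["start"])
            qsize = int(query_row.annotations["size"])
            if query_row.annotations["strand"] == 1:
                strand = "+"
                query_start = qstart_native
            else:
                strand = "-"
                src_size = int(query_row.annotations["srcSize"])
                query_start = src_size - qstart_native - qsize
            query_end = query_start + qsize
            block_annotations = getattr(block, "_annotations", None) or {}
            score = block_annotations.get("score")
            if score is None:
                score = block.get_alignment_length()
            fragments.append(
                AlignmentFragment(
                    ref_id=ref_row.id,
                    ref_start=ref_start,
                    ref_end=ref_end,
                    query_id=query_row.id,
                    query_start=query_start,
                    query_end=query_end,
                    strand=strand,
                    score=float(score),
                )
            )
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} MAF block(s) without exactly 2 sequences")
    result = AlignmentSet(reference=reference.name, query=query.name, fragments=fragments)
    result.validate_against(reference, query)
    return result
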