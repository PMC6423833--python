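"""Consensus segment block (CSB) construction.

A CSB is a one-to-one pair of intervals, one per assembly, built by chaining
collinear alignment fragments at a given *resolution*: the resolution is
both the minimum CSB length (on each genome) and the ceiling on the size of
unaligned gaps allowed inside a CSB.  Construction has two stages:

1. :func:`resolve_overlaps` makes the fragment set one-to-one — no two
   fragments may overlap on the reference or on the query.  Fragments are
   kept greedily in score order and lower-priority fragments are trimmed
   (proportionally on the partner genome) or dropped.
2. :func:`chain_fragments` merges runs of collinear, same-strand fragments
   whose inter-fragment gaps are shorter than the resolution on both
   genomes, then keeps every chain spanning at least the resolution on both
   genomes as a CSB.

This mirrors how synteny blocks are built from pairwise whole-genome
alignments, restricted to the two-assembly case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from intervaltree import IntervalTree

from .alignments import AlignmentFragment, AlignmentSet
from .assembly import Assembly

__all__ = ["CSB", "CSBSet", "resolve_overlaps", "chain_fragments", "build_csbs", "write_csb_tsv"]


@dataclass(frozen=True)
class CSB:
    """One consensus segment block: a chained pair of intervals."""

    ref_id: str
    ref_start: int
    ref_end: int
    query_id: str
    query_start: int
    query_end: int
    strand: str
    members: tuple[AlignmentFragment, ...] = ()

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


@dataclass
class CSBSet:
    """All CSBs built between two assemblies at one resolution.

    ``count`` is the same quantity seen from either assembly: a CSB is one
    block on each side by construction.  Coverages are the summed spans
    l(CSBs_1) and l(CSBs_2) entering the length score.
    """

    resolution_bp: int
    csbs: list[CSB] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.csbs)

    def __iter__(self):
        return iter(self.csbs)

    @property
    def count(self) -> int:
        return len(self.csbs)

    @property
    def ref_coverage_bp(self) -> int:
        return sum(c.ref_span for c in self.csbs)

    @property
    def query_coverage_bp(self) -> int:
        return sum(c.query_span for c in self.csbs)


def _map_ref_trim_to_query(frag: AlignmentFragment, new_ref_start: int, new_ref_end: int) -> Optional[AlignmentFragment]:
    """Shrink a fragment to a reference subinterval, scaling the query side.

    The query interval is trimmed by the same *fraction* as the reference
    interval, respecting strand: trimming the reference start of a '-'
    fragment trims the query end.  Returns None if either side collapses.
    """
    if new_ref_start >= new_ref_end:
        return None
    left_cut = new_ref_start - frag.ref_start
    right_cut = frag.ref_end - new_ref_end
    qlen = frag.query_length
    rlen = frag.ref_length
    q_left = round(qlen * left_cut / rlen)
    q_right = round(qlen * right_cut / rlen)
    if frag.strand == "+":
        new_q_start = frag.query_start + q_left
        new_q_end = frag.query_end - q_right
    else:
        new_q_start = frag.query_start + q_right
        new_q_end = frag.query_end - q_left
    if new_q_start >= new_q_end:
        return None
    return AlignmentFragment(
        ref_id=frag.ref_id,
        ref_start=new_ref_start,
        ref_end=new_ref_end,
        query_id=frag.query_id,
        query_start=new_q_start,
        query_end=new_q_end,
        strand=frag.strand,
        score=frag.score * (new_ref_end - new_ref_start) / rlen,
    )


def _map_query_trim_to_ref(frag: AlignmentFragment, new_q_start: int, new_q_end: int) -> Optional[AlignmentFragment]:
    """Mirror of :func:`_map_ref_trim_to_query` for a query-side trim."""
    if new_q_start >= new_q_end:
        return None
    left_cut = new_q_start - frag.query_start
    right_cut = frag.query_end - new_q_end
    qlen = frag.query_length
    rlen = frag.ref_length
    r_left = round(rlen * left_cut / qlen)
    r_right = round(rlen * right_cut / qlen)
    if frag.strand == "+":
        new_ref_start = frag.ref_start + r_left
        new_ref_end = frag.ref_end - r_right
    else:
        new_ref_start = frag.ref_start + r_right
        new_ref_end = frag.ref_end - r_left
    if new_ref_start >= new_ref_end:
        return None
    return AlignmentFragment(
        ref_id=frag.ref_id,
        ref_start=new_ref_start,
        ref_end=new_ref_end,
        query_id=frag.query_id,
        query_start=new_q_start,
        query_end=new_q_end,
        strand=frag.strand,
        score=frag.score * (new_q_end - new_q_start) / qlen,
    )


def _largest_free_subinterval(start: int, end: int, tree: IntervalTree) -> Optional[tuple[int, int]]:
    """The longest (leftmost on ties) part of [start, end) not covered by tree."""
    covered = sorted((iv.begin, iv.end) for iv in tree.overlap(start, end))
    free: list[tuple[int, int]] = []
    cursor = start
    for b, e in covered:
        if b > cursor:
            free.append((cursor, b))
        cursor = max(cursor, e)
    if cursor < end:
        free.append((cursor, end))
    if not free:
        return None
    return max(free, key=lambda iv: (iv[1] - iv[0], -iv[0]))


def resolve_overlaps(alignments: AlignmentSet) -> AlignmentSet:
    """Make alignment fragments one-to-one on both genomes.

    Fragments are processed by descending score (ties: ref_id then
    ref_start); each fragment is trimmed to the largest portion of its
    reference interval, then of its query interval, not already claimed by
    a higher-priority fragment, with the partner side scaled
    proportionally.  Fragments shrinking below 1 bp on either side are
    dropped.
    """
    order = sorted(
        alignments.fragments,
        key=lambda f: (-f.score, f.ref_id, f.ref_start, f.query_id, f.query_start),
    )
    ref_trees: dict[str, IntervalTree] = {}
    query_trees: dict[str, IntervalTree] = {}
    kept: list[AlignmentFragment] = []
    for frag in order:
        rtree = ref_trees.setdefault(frag.ref_id, IntervalTree())
        free_ref = _largest_free_subinterval(frag.ref_start, frag.ref_end, rtree)
        if free_ref is None:
            continue
        trimmed = _map_ref_trim_to_query(frag, *free_ref)
        if trimmed is None:
            continue
        qtree = query_trees.setdefault(trimmed.query_id, IntervalTree())
        free_query = _largest_free_subinterval(trimmed.query_start, trimmed.query_end, qtree)
        if free_query is None:
            continue
        trimmed = _map_query_trim_to_ref(trimmed, *free_query)
        if trimmed is None:
            continue
        rtree.addi(trimmed.ref_start, trimmed.ref_end)
        qtree.addi(trimmed.query_start, trimmed.query_end)
        kept.append(trimmed)
    kept.sort(key=lambda f: (f.ref_id, f.ref_start, f.query_id, f.query_start))
    return AlignmentSet(reference=alignments.reference, query=alignments.query, fragments=kept)


def _chainable(
    prev: AlignmentFragment,
    nxt: AlignmentFragment,
    resolution_bp: int,
    ref_trees: dict[str, IntervalTree],
    query_trees: dict[str, IntervalTree],
) -> bool:
    """Whether two ref-sorted same-group fragments may share a chain.

    Requires collinearity (query order consistent with strand) and a gap
    shorter than the resolution on both genomes.  The gap must be a truly
    *unaligned* run: if any other alignment fragment occupies part of it on
    either genome, the chain breaks there.  This keeps the spans of all
    CSBs pairwise non-overlapping per genome even when chains from
    different fragment pairs interleave.
    """
    ref_gap = nxt.ref_start - prev.ref_end
    if ref_gap < 0 or ref_gap >= resolution_bp:
        return False
    if prev.strand == "+":
        query_lo, query_hi = prev.query_end, nxt.query_start
    else:
        query_lo, query_hi = nxt.query_end, prev.query_start
    query_gap = query_hi - query_lo
    if not 0 <= query_gap < resolution_bp:
        return False
    if ref_gap > 0 and ref_trees[prev.ref_id].overlap(prev.ref_end, nxt.ref_start):
        return False
    if query_gap > 0 and query_trees[prev.query_id].overlap(query_lo, query_hi):
        return False
    return True


def _chain_to_csb(chain: list[AlignmentFragment], resolution_bp: int) -> Optional[CSB]:
    """Turn a maximal chain into a CSB if it spans >= resolution on both sides."""
    first, last = chain[0], chain[-1]
    ref_start, ref_end = first.ref_start, last.ref_end
    if first.strand == "+":
        query_start, query_end = first.query_start, last.query_end
    else:
        query_start, query_end = last.query_start, first.query_end
    if ref_end - ref_start < resolution_bp or query_end - query_start < resolution_bp:
        return None
    return CSB(
        ref_id=first.ref_id,
        ref_start=ref_start,
        ref_end=ref_end,
        query_id=first.query_id,
        query_start=query_start,
        query_end=query_end,
        strand=first.strand,
        members=tuple(chain),
    )


def chain_fragments(alignments: AlignmentSet, resolution_bp: int) -> CSBSet:
    """Chain overlap-free fragments into CSBs at the given resolution.

    Within each (ref_id, query_id, strand) group, fragments sorted by
    reference start are merged while consecutive pairs stay collinear with
    gaps shorter than the resolution on both genomes; every maximal chain
    spanning at least the resolution on both genomes becomes one CSB.
    """
    if resolution_bp < 1:
        raise ValueError(f"resolution_bp must be >= 1, got {resolution_bp}")
    groups: dict[tuple[str, str, str], list[AlignmentFragment]] = {}
    ref_trees: dict[str, IntervalTree] = {}
    query_trees: dict[str, IntervalTree] = {}
    for frag in alignments:
        groups.setdefault((frag.ref_id, frag.query_id, frag.strand), []).append(frag)
        ref_trees.setdefault(frag.ref_id, IntervalTree()).addi(frag.ref_start, frag.ref_end)
        query_trees.setdefault(frag.query_id, IntervalTree()).addi(frag.query_start, frag.query_end)
    csbs: list[CSB] = []
    for key in sorted(groups):
        frags = sorted(groups[key], key=lambda f: (f.ref_start, f.query_start))
        chain: list[AlignmentFragment] = []
        for frag in frags:
            if chain and _chainable(chain[-1], frag, resolution_bp, ref_trees, query_trees):
                chain.append(frag)
            else:
                if chain:
                    csb = _chain_to_csb(chain, resolution_bp)
                    if csb is not None:
                        csbs.append(csb)
                chain = [frag]
        if chain:
            csb = _chain_to_csb(chain, resolution_bp)
            if csb is not None:
                csbs.append(csb)
    csbs.sort(key=lambda c: (c.ref_id, c.ref_start, c.query_id, c.query_start))
    return CSBSet(resolution_bp=resolution_bp, csbs=csbs)


def build_csbs(
    reference: Assembly,
    query: Assembly,
    alignments: AlignmentSet,
    resolution_bp: int,
) -> CSBSet:
    """Full CSB construction at one resolution.

    Alignments are first restricted to fragments lying on assembly
    sequences strictly longer than the resolution (matching the filtered
    l(A) and c(A) quantities), then overlap-resolved and chained.
    """
    ref_lengths = reference.lengths
    query_lengths = query.lengths
    surviving = [
        f
        for f in alignments
        if ref_lengths.get(f.ref_id, 0) > resolution_bp
        and query_lengths.get(f.query_id, 0) > resolution_bp
    ]
    filtered = AlignmentSet(alignments.reference, alignments.query, surviving)
    return chain_fragments(resolve_overlaps(filtered), resolution_bp)


def write_csb_tsv(csb_set: CSBSet, path: Union[str, Path]) -> None:
    """Write CSBs as paired-BED-like TSV (0-based half-open coordinates)."""
    with open(path, "w") as handle:
        handle.write(
            "#ref_id\tref_start\tref_end\tquery_id\tquery_start\tquery_end\tstrand\tcsb_index\n"
        )
        for idx, csb in enumerate(csb_set):
            handle.write(
                f"{csb.ref_id}\t{csb.ref_start}\t{csb.ref_end}\t{csb.query_id}\t"
                f"{csb.query_start}\t{csb.query_end}\t{csb.strand}\t{idx}\n"
            )
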