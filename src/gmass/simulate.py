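"""Synthetic assembly pairs with controlled structural divergence.

The simulator produces a random ancestral assembly and evolves descendant
assemblies from it by applying, in a fixed order, translocations and
inversions (segment cut/paste and reverse-complement), then indels, then
point substitutions, then optional refragmentation.  Because every derived
fragment is tracked as a list of *pieces* — each either a strand-aware
interval of an ancestral fragment or an inserted run of novel sequence —
the exact ground-truth alignment between ancestor and descendant falls out
of the bookkeeping: one gapless alignment fragment per mapped piece.

The ground truth plays the role of an external aligner's output, so the
whole scoring pipeline can be exercised without running an aligner: truth
fragments tile each derived assembly (minus inserted material), never
overlap on either genome, and carry the correct orientation.

A :func:`divergence_series` scales one base divergence specification by a
list of multipliers, emulating a family of descendants at increasing
evolutionary distance from a common reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .assembly import Assembly, SequenceRecord
from .alignments import AlignmentFragment, AlignmentSet, write_paf
from .errors import GmassError

__all__ = [
    "DivergenceSpec",
    "simulate_ancestor",
    "evolve",
    "divergence_series",
    "desk_preset",
    "write_simulation",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i
    _BASE_INDEX[_b + 32] = _i  # lowercase

MIN_FRAGMENT_LENGTH = 100


@dataclass(frozen=True)
class DivergenceSpec:
    """How far a descendant is perturbed away from its ancestor.

    Rates are per base; event counts are totals over the whole genome.
    Indel lengths are geometric with the given mean; inversion and
    translocation segment lengths are uniform within ``segment_length_range``
    (chosen to interact with the CSB resolution scale).  The same spec and
    seed always reproduce the same descendant.
    """

    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    indel_mean_length: float = 20.0
    n_inversions: int = 0
    n_translocations: int = 0
    breakpoint_count: int = 0
    segment_length_range: tuple[int, int] = (5_000, 30_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must be in [0, 1]")
        if not 0.0 <= self.indel_rate <= 1.0:
            raise ValueError("indel_rate must be in [0, 1]")
        if self.indel_mean_length < 1:
            raise ValueError("indel_mean_length must be >= 1")
        if min(self.n_inversions, self.n_translocations, self.breakpoint_count) < 0:
            raise ValueError("event counts must be >= 0")
        lo, hi = self.segment_length_range
        if not 1 <= lo <= hi:
            raise ValueError("segment_length_range must satisfy 1 <= lo <= hi")

    def scaled(self, multiplier: float, seed: int) -> "DivergenceSpec":
        """The same spec with rates and event counts scaled by a multiplier."""
        if multiplier < 0:
            raise ValueError("multiplier must be >= 0")
        return replace(
            self,
            substitution_rate=min(1.0, self.substitution_rate * multiplier),
            indel_rate=min(1.0, self.indel_rate * multiplier),
            n_inversions=int(round(self.n_inversions * multiplier)),
            n_translocations=int(round(self.n_translocations * multiplier)),
            breakpoint_count=int(round(self.breakpoint_count * multiplier)),
            seed=seed,
        )


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _to_string(indices: np.ndarray) -> str:
    return _BASES[indices].tobytes().decode("ascii")


def simulate_ancestor(total_length: int, n_fragments: int, seed: int) -> Assembly:
    """A random ancestral assembly of ``n_fragments`` summing to ``total_length``.

    Fragment lengths are drawn around the even split (each at least
    ``MIN_FRAGMENT_LENGTH`` bp) and the sequences are uniform random
    nucleotides; the same seed reproduces the same assembly.
    """
    if n_fragments < 1:
        raise GmassError("n_fragments must be >= 1")
    if total_length < n_fragments * MIN_FRAGMENT_LENGTH:
        raise GmassError(
            f"total_length {total_length} cannot hold {n_fragments} fragments of "
            f"at least {MIN_FRAGMENT_LENGTH} bp each"
        )
    rng = np.random.default_rng(seed)
    # jitter around the even split, then repair the rounding remainder
    weights = rng.dirichlet(np.full(n_fragments, 20.0))
    spare = total_length - n_fragments * MIN_FRAGMENT_LENGTH
    lengths = (MIN_FRAGMENT_LENGTH + np.floor(weights * spare)).astype(int)
    lengths[0] += total_length - int(lengths.sum())
    records = [
        SequenceRecord(f"anc_{k + 1}", int(length), _to_string(_random_sequence(rng, int(length))))
        for k, length in enumerate(lengths)
    ]
    return Assembly("ancestor", records)


@dataclass
class _Piece:
    """One run of a derived fragment: ancestral interval or novel insertion."""

    src_id: Optional[str]  # None for inserted material
    src_start: int
    src_end: int
    strand: str
    insert_seq: Optional[np.ndarray] = None

    @property
    def length(self) -> int:
        if self.src_id is None:
            return len(self.insert_seq)
        return self.src_end - self.src_start

    def split(self, offset: int) -> tuple["_Piece", "_Piece"]:
        """Split into derived-order (left, right) parts at a derived offset."""
        if not 0 < offset < self.length:
            raise ValueError("split offset must be interior")
        if self.src_id is None:
            return (
                _Piece(None, 0, 0, "+", self.insert_seq[:offset]),
                _Piece(None, 0, 0, "+", self.insert_seq[offset:]),
            )
        if self.strand == "+":
            mid = self.src_start + offset
            return (
                _Piece(self.src_id, self.src_start, mid, "+"),
                _Piece(self.src_id, mid, self.src_end, "+"),
            )
        mid = self.src_end - offset
        return (
            _Piece(self.src_id, mid, self.src_end, "-"),
            _Piece(self.src_id, self.src_start, mid, "-"),
        )

    def reverse_complement(self) -> "_Piece":
        if self.src_id is None:
            return _Piece(None, 0, 0, "+", (3 - self.insert_seq)[::-1])
        return _Piece(
            self.src_id,
            self.src_start,
            self.src_end,
            "-" if self.strand == "+" else "+",
        )


def _fragment_length(pieces: list[_Piece]) -> int:
    return sum(p.length for p in pieces)


def _split_pieces(pieces: list[_Piece], pos: int) -> tuple[list[_Piece], list[_Piece]]:
    """Split a piece list at derived position ``pos``."""
    left: list[_Piece] = []
    cursor = 0
    for idx, piece in enumerate(pieces):
        if cursor + piece.length <= pos:
            left.append(piece)
            cursor += piece.length
            continue
        if cursor == pos:
            return left, pieces[idx:]
        a, b = piece.split(pos - cursor)
        left.append(a)
        return left, [b] + pieces[idx + 1 :]
    return left, []


def _extract(pieces: list[_Piece], start: int, end: int) -> tuple[list[_Piece], list[_Piece]]:
    """Remove derived interval [start, end); returns (remaining, removed)."""
    head, tail = _split_pieces(pieces, start)
    mid, rest = _split_pieces(tail, end - start)
    return head + rest, mid


def _insert(pieces: list[_Piece], pos: int, segment: list[_Piece]) -> list[_Piece]:
    head, tail = _split_pieces(pieces, pos)
    return head + segment + tail


def _pick_segment(
    rng: np.random.Generator, fragments: list[list[_Piece]], spec: DivergenceSpec
) -> tuple[int, int, int]:
    """Choose (fragment index, start, end) for a rearrangement event."""
    lo, hi = spec.segment_length_range
    lengths = [_fragment_length(p) for p in fragments]
    eligible = [k for k, length in enumerate(lengths) if length > lo]
    if not eligible:
        raise GmassError(
            f"no fragment longer than the minimum event segment ({lo} bp)"
        )
    weights = np.array([lengths[k] for k in eligible], dtype=float)
    frag_idx = eligible[rng.choice(len(eligible), p=weights / weights.sum())]
    seg_len = int(rng.integers(lo, min(hi, lengths[frag_idx] - 1) + 1))
    start = int(rng.integers(0, lengths[frag_idx] - seg_len + 1))
    return frag_idx, start, start + seg_len


def evolve(ancestor: Assembly, spec: DivergenceSpec) -> tuple[Assembly, AlignmentSet]:
    """Evolve a descendant assembly and its ground-truth alignment.

    Events are applied in a fixed order — translocations, inversions,
    indels, refragmentation — and substitutions are added when the derived
    sequences are rendered, so truth coordinates are computed once.  The
    truth set maps every conserved derived run back to its ancestral
    interval with the correct strand; it tiles the descendant except for
    inserted material and omits deleted ancestral material.
    """
    for rec in ancestor:
        if rec.sequence is None:
            raise GmassError(f"ancestor fragment {rec.id!r} has no sequence")
    rng = np.random.default_rng(spec.seed)
    fragments: list[list[_Piece]] = [
        [_Piece(rec.id, 0, rec.length, "+")] for rec in ancestor
    ]

    for _ in range(spec.n_translocations):
        frag_idx, start, end = _pick_segment(rng, fragments, spec)
        remaining, segment = _extract(fragments[frag_idx], start, end)
        fragments[frag_idx] = remaining
        dest = int(rng.integers(0, len(fragments)))
        pos = int(rng.integers(0, _fragment_length(fragments[dest]) + 1))
        fragments[dest] = _insert(fragments[dest], pos, segment)

    for _ in range(spec.n_inversions):
        frag_idx, start, end = _pick_segment(rng, fragments, spec)
        remaining, segment = _extract(fragments[frag_idx], start, end)
        inverted = [p.reverse_complement() for p in reversed(segment)]
        fragments[frag_idx] = _insert(remaining, start, inverted)

    if spec.indel_rate > 0:
        for k in range(len(fragments)):
            length = _fragment_length(fragments[k])
            n_events = rng.poisson(spec.indel_rate * length)
            for _ in range(n_events):
                size = int(rng.geometric(1.0 / spec.indel_mean_length))
                length = _fragment_length(fragments[k])
                if rng.random() < 0.5 and length > size + 1:  # deletion
                    start = int(rng.integers(0, length - size))
                    fragments[k], _removed = _extract(fragments[k], start, start + size)
                else:  # insertion of novel sequence
                    pos = int(rng.integers(0, length + 1))
                    novel = _Piece(None, 0, 0, "+", _random_sequence(rng, size))
                    fragments[k] = _insert(fragments[k], pos, [novel])

    for _ in range(spec.breakpoint_count):
        lengths = [_fragment_length(p) for p in fragments]
        splittable = [k for k, length in enumerate(lengths) if length >= 2]
        if not splittable:
            break
        weights = np.array([lengths[k] for k in splittable], dtype=float)
        frag_idx = splittable[rng.choice(len(splittable), p=weights / weights.sum())]
        pos = int(rng.integers(1, lengths[frag_idx]))
        left, right = _split_pieces(fragments[frag_idx], pos)
        fragments[frag_idx] = left
        fragments.append(right)

    fragments = [p for p in fragments if _fragment_length(p) > 0]

    # render sequences (substitutions applied here) and emit the truth set
    ancestral_idx = {
        rec.id: _BASE_INDEX[np.frombuffer(rec.sequence.encode(), dtype=np.uint8)]
        for rec in ancestor
    }
    records: list[SequenceRecord] = []
    truth: list[AlignmentFragment] = []
    for k, pieces in enumerate(fragments):
        name = f"der_{k + 1}"
        chunks: list[np.ndarray] = []
        offset = 0
        for piece in pieces:
            if piece.src_id is None:
                chunks.append(piece.insert_seq)
            else:
                segment = ancestral_idx[piece.src_id][piece.src_start : piece.src_end]
                if piece.strand == "-":
                    segment = (3 - segment)[::-1]
                chunks.append(segment)
                truth.append(
                    AlignmentFragment(
                        ref_id=piece.src_id,
                        ref_start=piece.src_start,
                        ref_end=piece.src_end,
                        query_id=name,
                        query_start=offset,
                        query_end=offset + piece.length,
                        strand=piece.strand,
                        score=piece.length,
                    )
                )
            offset += piece.length
        seq = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.uint8)
        if spec.substitution_rate > 0:
            mask = rng.random(len(seq)) < spec.substitution_rate
            shifts = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
            seq = seq.copy()
            seq[mask] = (seq[mask] + shifts) % 4
        records.append(SequenceRecord(name, len(seq), _to_string(seq)))
    derived = Assembly("derived", records)
    return derived, AlignmentSet(reference=ancestor.name, query=derived.name, fragments=truth)


def _level_seed(master_seed: int, level_index: int) -> int:
    # one master seed deterministically fans out to per-level seeds
    return (master_seed * 100_003 + 7_919 * level_index + 1) % 2**31


def divergence_series(
    ancestor: Assembly,
    base_spec: DivergenceSpec,
    levels: Sequence[float],
) -> list[tuple[float, Assembly, AlignmentSet]]:
    """One descendant per divergence level (multiplier on the base spec)."""
    if len(levels) < 2:
        raise GmassError("a divergence series needs at least 2 levels")
    series = []
    for idx, level in enumerate(levels):
        spec = base_spec.scaled(level, seed=_level_seed(base_spec.seed, idx))
        derived, truth = evolve(ancestor, spec)
        derived.name = f"derived_L{idx}"
        truth.query = derived.name
        series.append((float(level), derived, truth))
    return series


def desk_preset(seed: int = 0) -> tuple[Assembly, DivergenceSpec, list[int]]:
    """Desk-scale defaults: 500 Kbp ancestor in 2 fragments, 10–50 Kbp resolutions.

    This is the study design scaled down by 10x from Mbp-scale chromosomes
    probed at 100–500 Kbp resolutions, keeping every ratio (segment sizes
    to resolution, resolution to fragment length) intact.
    """
    ancestor = simulate_ancestor(total_length=500_000, n_fragments=2, seed=seed)
    base_spec = DivergenceSpec(
        substitution_rate=0.05,
        indel_rate=0.001,
        indel_mean_length=20.0,
        n_inversions=12,
        n_translocations=6,
        breakpoint_count=4,
        segment_length_range=(5_000, 30_000),
        seed=seed,
    )
    resolutions = [10_000, 20_000, 30_000, 40_000, 50_000]
    return ancestor, base_spec, resolutions


def write_simulation(
    outdir: Union[str, Path],
    ancestor: Assembly,
    derived: Assembly,
    truth: AlignmentSet,
    spec: DivergenceSpec,
) -> None:
    """Write a simulated pair as FASTA x2 + truth PAF + JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for assembly, filename in ((ancestor, "ancestor.fa"), (derived, "derived.fa")):
        with open(outdir / filename, "w") as handle:
            for rec in assembly:
                handle.write(f">{rec.id}\n")
                for i in range(0, rec.length, 80):
                    handle.write(rec.sequence[i : i + 80] + "\n")
    write_paf(truth, outdir / "truth.paf", ancestor, derived)
    manifest = {
        "ancestor": ancestor.name,
        "derived": derived.name,
        "substitution_rate": spec.substitution_rate,
        "indel_rate": spec.indel_rate,
        "indel_mean_length": spec.indel_mean_length,
        "n_inversions": spec.n_inversions,
        "n_translocations": spec.n_translocations,
        "breakpoint_count": spec.breakpoint_count,
        "segment_length_range": list(spec.segment_length_range),
        "seed": spec.seed,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
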