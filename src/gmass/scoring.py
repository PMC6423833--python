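"""The GMASS score: structural similarity of two genome assemblies.

At each resolution *i* two per-resolution scores are combined:

* the length score ``L_i = (l(CSBs_1) + l(CSBs_2)) / (l(A_1) + l(A_2))`` —
  the fraction of the resolution-filtered assembly length covered by CSBs;
* the count score ``C_i`` — how close the CSB count is to the filtered
  fragment counts.  When ``c(A_1) + c(A_2) >= 2*c(CSBs)`` it is the plain
  ratio ``2*c(CSBs) / (c(A_1) + c(A_2))``; otherwise the CSB excess is
  penalised against the headroom left by ``maxc(A_x) = floor(l(A_x)/i)``,
  the most CSBs of minimum length *i* that could fit:
  ``C_i = 1 - (2*c(CSBs) - c(A_1) - c(A_2)) / (maxc(A_1) + maxc(A_2) -
  c(A_1) - c(A_2))``.

The structural similarity at one resolution is ``S_i = L_i * C_i`` and the
GMASS score is the mean of ``S_i`` over the resolution set — either a fixed
list (default 100–500 Kbp) or the N50–N90 values of the non-reference
assembly.  All scores lie in [0, 1]; 1 means the assemblies are
structurally identical at every probed resolution.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

from .assembly import Assembly, filter_fragments, nx_statistic
from .alignments import AlignmentSet
from .csb import CSBSet, build_csbs
from .errors import EmptyResolutionError

__all__ = [
    "ResolutionScores",
    "GmassResult",
    "length_score",
    "count_score",
    "max_csb_count",
    "structural_similarity",
    "gmass",
    "choose_reference",
    "resolution_set",
    "score_at_resolution",
    "score_pair",
    "DEFAULT_FIXED_RESOLUTIONS",
    "NX_FRACTIONS",
]

DEFAULT_FIXED_RESOLUTIONS: tuple[int, ...] = (100_000, 200_000, 300_000, 400_000, 500_000)
NX_FRACTIONS: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9)


def length_score(l_csb1: int, l_csb2: int, l_A1: int, l_A2: int) -> float:
    """Length score L: fraction of filtered assembly length inside CSBs."""
    if l_A1 + l_A2 <= 0:
        raise EmptyResolutionError("no comparable sequence at this resolution")
    if l_csb1 > l_A1 or l_csb2 > l_A2:
        raise ValueError("CSB coverage cannot exceed filtered assembly length")
    return (l_csb1 + l_csb2) / (l_A1 + l_A2)


def max_csb_count(l_Ax: int, resolution_bp: int) -> int:
    """Most CSBs of minimum length ``resolution_bp`` that fit in ``l_Ax`` bp."""
    if resolution_bp < 1:
        raise ValueError(f"resolution_bp must be >= 1, got {resolution_bp}")
    return l_Ax // resolution_bp


def count_score(c_csb: int, c_A1: int, c_A2: int, maxc_A1: int, maxc_A2: int) -> float:
    """Count score C: similarity of CSB count to filtered fragment counts.

    The upper branch rewards CSB counts at or below the fragment counts;
    the lower branch penalises an excess of CSBs against the remaining
    capacity ``maxc(A_1) + maxc(A_2) - c(A_1) - c(A_2)``.  Both branches
    agree (C = 1) when the counts match exactly, and they coincide at the
    boundary ``2*c_csb = c_A1 + c_A2``.
    """
    if c_A1 + c_A2 == 0:
        raise EmptyResolutionError("no comparable sequence at this resolution")
    if c_csb > min(maxc_A1, maxc_A2):
        raise ValueError(
            f"CSB count {c_csb} exceeds the capacity bound min({maxc_A1}, {maxc_A2})"
        )
    if c_A1 + c_A2 >= 2 * c_csb:
        return 2 * c_csb / (c_A1 + c_A2)
    denominator = maxc_A1 + maxc_A2 - c_A1 - c_A2
    if denominator == 0:
        return 1.0
    return 1.0 - (2 * c_csb - c_A1 - c_A2) / denominator


def structural_similarity(L: float, C: float) -> float:
    """Per-resolution structural similarity S = L * C."""
    return L * C


@dataclass(frozen=True)
class ResolutionScores:
    """Every per-resolution quantity entering the GMASS score."""

    resolution_bp: int
    l_A1: int
    l_A2: int
    c_A1: int
    c_A2: int
    l_csb1: int
    l_csb2: int
    c_csb: int
    maxc_A1: int
    maxc_A2: int
    L: float
    C: float
    S: float
    branch: str  # "upper" or "lower" arm of the count score

    def as_dict(self) -> dict:
        d = asdict(self)
        d["i"] = d.pop("resolution_bp")
        return d


@dataclass
class GmassResult:
    """The final score with full per-resolution provenance."""

    reference_name: str
    query_name: str
    mode: str  # "fixed" or "nx"
    resolutions: list[int]
    per_resolution: list[ResolutionScores]
    gmass: float
    notes: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.resolutions)

    def to_json(self, path: Union[str, Path, None] = None, indent: int = 2) -> str:
        payload = {
            "reference": self.reference_name,
            "query": self.query_name,
            "mode": self.mode,
            "resolutions": self.resolutions,
            "per_resolution": [s.as_dict() for s in self.per_resolution],
            "gmass": self.gmass,
            "notes": self.notes,
        }
        text = json.dumps(payload, indent=indent)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_tsv(self, path: Union[str, Path, None] = None) -> str:
        lines = ["combination\tresolution\tL\tC\tS"]
        combo = f"{self.reference_name}-{self.query_name}"
        for s in self.per_resolution:
            lines.append(f"{combo}\t{s.resolution_bp}\t{s.L:.3f}\t{s.C:.3f}\t{s.S:.3f}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def summary(self) -> str:
        return f"GMASS = {self.gmass:.3f}"


def gmass(per_resolution: Sequence[ResolutionScores]) -> float:
    """Arithmetic mean of the per-resolution structural similarities."""
    if not per_resolution:
        raise ValueError("at least one resolution is required")
    return sum(s.S for s in per_resolution) / len(per_resolution)


def choose_reference(A1: Assembly, A2: Assembly) -> tuple[Assembly, Assembly, bool]:
    """Pick the assembly with the higher N50 as reference.

    Returns ``(reference, query, tied)``; on an N50 tie the first argument
    is the reference and ``tied`` is True.
    """
    n50_1 = nx_statistic(A1, 0.5)
    n50_2 = nx_statistic(A2, 0.5)
    if n50_2 > n50_1:
        return A2, A1, False
    return A1, A2, n50_1 == n50_2


def resolution_set(
    mode: str,
    reference: Assembly,
    query: Assembly,
    fixed_list: Optional[Sequence[int]] = None,
) -> list[int]:
    """Build the ordered resolution set.

    ``fixed`` mode returns the given list (default 100–500 Kbp).  ``nx``
    mode returns the N50, N60, N70, N80 and N90 of the *non-reference*
    (query) assembly, computed on its unfiltered fragment lengths.  Equal
    values are collapsed with a warning, reducing n.
    """
    if mode == "fixed":
        resolutions = list(fixed_list) if fixed_list is not None else list(DEFAULT_FIXED_RESOLUTIONS)
        if any(r < 1 for r in resolutions):
            raise ValueError("resolutions must be positive")
    elif mode == "nx":
        resolutions = [nx_statistic(query, x) for x in NX_FRACTIONS]
    else:
        raise ValueError(f"mode must be 'fixed' or 'nx', got {mode!r}")
    deduplicated: list[int] = []
    for r in resolutions:
        if r not in deduplicated:
            deduplicated.append(r)
    if len(deduplicated) < len(resolutions):
        warnings.warn(
            f"resolution set contains duplicates; n reduced from "
            f"{len(resolutions)} to {len(deduplicated)}"
        )
    if not deduplicated:
        raise ValueError("resolution set is empty")
    return deduplicated


def score_at_resolution(
    reference: Assembly,
    query: Assembly,
    alignments: AlignmentSet,
    resolution_bp: int,
    csb_set: Optional[CSBSet] = None,
) -> ResolutionScores:
    """Compute L, C and S for one resolution (building CSBs if not given)."""
    stats1 = filter_fragments(reference, resolution_bp)
    stats2 = filter_fragments(query, resolution_bp)
    if stats1.fragment_count == 0 or stats2.fragment_count == 0:
        raise EmptyResolutionError(
            f"no fragment longer than resolution {resolution_bp} in "
            f"{'both' if stats1.fragment_count == stats2.fragment_count == 0 else 'one of'} "
            "the assemblies"
        )
    if csb_set is None:
        csb_set = build_csbs(reference, query, alignments, resolution_bp)
    l_A1, l_A2 = stats1.total_length_bp, stats2.total_length_bp
    c_A1, c_A2 = stats1.fragment_count, stats2.fragment_count
    l_csb1, l_csb2 = csb_set.ref_coverage_bp, csb_set.query_coverage_bp
    c_csb = csb_set.count
    maxc_A1 = max_csb_count(l_A1, resolution_bp)
    maxc_A2 = max_csb_count(l_A2, resolution_bp)
    L = length_score(l_csb1, l_csb2, l_A1, l_A2)
    C = count_score(c_csb, c_A1, c_A2, maxc_A1, maxc_A2)
    return ResolutionScores(
        resolution_bp=resolution_bp,
        l_A1=l_A1,
        l_A2=l_A2,
        c_A1=c_A1,
        c_A2=c_A2,
        l_csb1=l_csb1,
        l_csb2=l_csb2,
        c_csb=c_csb,
        maxc_A1=maxc_A1,
        maxc_A2=maxc_A2,
        L=L,
        C=C,
        S=structural_similarity(L, C),
        branch="upper" if c_A1 + c_A2 >= 2 * c_csb else "lower",
    )


def score_pair(
    A1: Assembly,
    A2: Assembly,
    alignments: AlignmentSet,
    mode: str = "nx",
    fixed_resolutions: Optional[Sequence[int]] = None,
    skip_empty_resolutions: bool = False,
) -> GmassResult:
    """End-to-end GMASS score between two assemblies.

    The assembly with the higher N50 becomes the reference; the alignment
    set is reoriented if it was produced with the other assembly as
    target.  CSBs are built and scored at every resolution; resolutions
    leaving no comparable fragment either abort (default) or are dropped
    with a note when ``skip_empty_resolutions`` is set.
    """
    reference, query, tied = choose_reference(A1, A2)
    notes: list[str] = []
    if tied:
        notes.append("N50 tie: first assembly kept as reference")
    if alignments.reference == query.name and alignments.query == reference.name:
        alignments = alignments.swapped()
        notes.append("alignment set reoriented to match the chosen reference")
    resolutions = resolution_set(mode, reference, query, fixed_resolutions)
    per_resolution: list[ResolutionScores] = []
    kept_resolutions: list[int] = []
    for res in resolutions:
        try:
            scores = score_at_resolution(reference, query, alignments, res)
        except EmptyResolutionError:
            if skip_empty_resolutions:
                notes.append(f"resolution {res} dropped: no surviving fragment")
                continue
            raise
        per_resolution.append(scores)
        kept_resolutions.append(res)
    if not per_resolution:
        raise EmptyResolutionError("every resolution left no comparable sequence")
    return GmassResult(
        reference_name=reference.name,
        query_name=query.name,
        mode=mode,
        resolutions=kept_resolutions,
        per_resolution=per_resolution,
        gmass=gmass(per_resolution),
        notes=notes,
    )
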