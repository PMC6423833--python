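# Methods

## The score

GMASS measures the structural similarity of two genome assemblies from the
number and total length of consensus segment blocks (CSBs) built between
them over a set of resolutions. The model's central assumption is that for
structurally similar assemblies the CSBs converge toward the assemblies'
own fragments: coverage approaches the full (resolution-filtered) assembly
length, and the block count approaches the fragment count. Divergence
breaks blocks apart, which either lowers coverage (fine structure falls
below the minimum block length) or inflates the block count past the
fragment count — the two failure modes that coverage-only or count-only
measures cannot separate.

At resolution *i* (bp), with l(A_x)/c(A_x) the total length and count of
fragments strictly longer than *i*:

* L_i = (l(CSBs_1)+l(CSBs_2)) / (l(A_1)+l(A_2)) ∈ [0,1];
* C_i = (c(CSBs_1)+c(CSBs_2)) / (c(A_1)+c(A_2)) when the fragment counts
  dominate, else 1 − (excess of CSBs) / (maxc(A_1)+maxc(A_2)−c(A_1)−c(A_2))
  with maxc(A_x) = ⌊l(A_x)/i⌋. Both arms coincide at the boundary
  2·c(CSBs) = c(A_1)+c(A_2), so C_i is continuous in the counts.
* S_i = L_i·C_i, GMASS = mean of S_i over the resolution set.

The capacity bound maxc uses floor division: counts are integers, and the
floor is the conservative number of disjoint blocks of length ≥ *i* that
fit in l(A_x) bp. Because every CSB spans at least *i* on each genome and
CSB spans are pairwise disjoint per genome, c(CSBs) ≤ min(maxc(A_1),
maxc(A_2)) holds constructively and the penalty branch can never go below
zero. A zero lower-branch denominator (fragments already saturate the
capacity) returns C_i = 1; it can only co-occur with zero excess.

The assembly with the higher N50 is the reference (ties keep the first
argument and are recorded in the result's notes). Two resolution modes are
provided: a fixed list, defaulting to 100, 200, 300, 400, 500 Kbp, and
`nx`, which uses the N50, N60, N70, N80 and N90 of the non-reference
assembly, computed on its unfiltered fragment lengths. Equal Nx values are
collapsed (with a warning), reducing *n* accordingly. A resolution that
leaves no fragment in either assembly aborts scoring by default; with
`skip_empty_resolutions` it is dropped from the set and noted in the
result provenance instead.

## CSB construction

Inputs are local alignment fragments (PAF or MAF) stored 0-based
half-open with forward-strand query coordinates. Construction at
resolution *i*:

1. **Fragment filtering.** Alignments on assembly sequences not strictly
   longer than *i* are removed, so CSBs live inside the same fragment set
   that defines l(A_x) and c(A_x). "Longer than the resolution" is strict
   (> *i*) throughout.
2. **Overlap resolution.** Fragments are made one-to-one on both genomes.
   Processing in descending score order (ties: ref id, ref start), each
   fragment keeps the largest unclaimed sub-interval of its reference
   interval, then of its query interval; the partner side is trimmed by
   the same fraction (strand-aware, `round()` to integer bp), and
   fragments that collapse below 1 bp on either side are dropped. The
   proportional trim is within ±1 bp of any base-exact scheme, immaterial
   at the ≥10 Kbp resolutions the score uses. Where a higher-priority
   fragment splits a lower one in the middle, the largest (leftmost on
   ties) remaining piece is kept — a whole-fragment decision that keeps the
   procedure deterministic.
3. **Chaining.** Within each (reference sequence, query sequence, strand)
   group, fragments sorted by reference start are merged while consecutive
   pairs are collinear (query order consistent with strand) and the gap
   between them is an *unaligned* run shorter than *i* on **both** genomes.
   "Unaligned" is load-bearing: if any other fragment occupies part of the
   gap on either genome, the chain breaks there. This is what guarantees
   that CSB spans never overlap — without it, chains from different
   sequence pairs can tunnel across each other's members, and block
   coverage could exceed assembly length.
4. **Span test.** Each maximal chain whose end-to-end extent (including
   internal small gaps — block extent, not aligned-base sum) is at least
   *i* on both genomes becomes one CSB; shorter chains are discarded.

Chaining is greedy within the sorted order rather than score-optimal DP:
after one-to-one overlap resolution collinear runs are unambiguous, and a
brute-force enumeration oracle over all maximal chains guards the
implementation on hundreds of random small instances in the test suite.
Opposite-strand fragments never co-chain; self-alignments are ordinary
inputs. Both the two-sided gap rule and the two-sided minimum-span rule are
deliberate choices: a one-sided reading exists, but the capacity bound must
hold from either assembly's viewpoint, and two-sided thresholds match
standard synteny-block construction.

## The simulator

`gmass.simulate` emulates the ancestor-plus-diverged-descendants study
design at desk scale. A random ancestor (uniform nucleotides, fragment
lengths jittered around the even split) is perturbed by, in fixed order:
translocations (segment cut/paste, possibly across fragments), inversions
(segment reverse-complement), indels (Poisson event counts, geometric
lengths), refragmentation (extra breakpoints), and point substitutions
applied at render time. Each derived fragment is maintained as a list of
pieces pointing back to ancestral intervals, so the exact ground-truth
alignment — one gapless fragment per conserved piece, correct strand —
falls out of the bookkeeping and substitutes for an external aligner's
output. Event order is fixed so truth coordinates are computed once.

Defaults (the `desk_preset`): a 500 Kbp ancestor in 2 fragments scored at
resolutions 10–50 Kbp — the Mbp-scale-chromosome / 100–500 Kbp-resolution
design scaled down tenfold with every ratio preserved; at full divergence
(level 1.0) substitution rate 0.05/bp, indel rate 0.001/bp with mean
length 20 bp, 12 inversions, 6 translocations, 4 extra breakpoints, and
rearrangement segment lengths uniform in [5, 30] Kbp = [i/2, 3i] at the
10 Kbp base resolution so events interact with the probed scales. A
divergence series scales rates and event counts linearly by per-level
multipliers (default levels 0, 0.1, …, 1.0 → 11 descendants); one master
seed fans out deterministically to per-level seeds, and all seeds stay
below 2³¹.

What the simulator does *not* emulate: alignment noise and alignment
breakage at high substitution density (truth fragments are exact, so
substitutions affect sequences but not block structure — divergence acts
on the score through rearrangements, indels and fragmentation); repeats
and repeat masking; N-gaps; realistic base composition; any calibrated
correspondence between the level multiplier and an evolutionary distance
in substitutions/site. Passing the divergence-monotonicity test therefore
demonstrates that the score tracks *structural* perturbation, not that it
reproduces any particular published correlation magnitude on real data.

## Numerical and edge-case choices

* All coordinates integer bp; scores are IEEE doubles; GMASS is an exact
  arithmetic mean (no weighting).
* Nx ties are broken by descending length then lexical id; Nx is computed
  by cumulative scan with a `isclose` guard against float threshold error.
* Fragment lengths count every residue including N and soft-masked bases.
* Empty alignment sets are valid and yield L = 0, hence S = 0.
* Human-readable output rounds to 3 decimals; JSON keeps full precision.

## Problem sizes

The test suite and the acceptance script run the simulator at 40–500 Kbp
genome scale (the desk preset), the chaining oracle on ≤ 8 fragments over
≥ 200 random instances, and the worked-example arithmetic directly; the
full suite completes in well under a minute.

## Known limitations

* The score depends on an externally produced alignment set for real
  assemblies; aligner parameters change CSBs and therefore the score.
* Greedy overlap trimming keeps one piece of a split fragment; a
  base-exact multi-piece scheme could retain slightly more alignment.
* Resolutions larger than most fragments discard most of the assembly
  (inherent to the resolution-filtering definition); the `nx` mode exists
  precisely because no fixed resolution set suits all contiguities.
* Only pairwise comparison is scored; all-pairs matrices are a loop for
  the caller.
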