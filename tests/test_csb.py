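"""CSB construction: overlap resolution and chaining, checked against
independent brute-force oracles on small random instances."""

import random

import pytest

from gmass import (
    AlignmentSet,
    build_csbs,
    chain_fragments,
    filter_fragments,
    resolve_overlaps,
)

from conftest import make_assembly, frag, aln_set


# --- independent oracles ---------------------------------------------------


def occupied(fragments, side):
    """Per-(sequence, base) occupancy sets, one per genome side."""
    cells = set()
    for f in fragments:
        if side == "ref":
            cells.update((f.ref_id, p) for p in range(f.ref_start, f.ref_end))
        else:
            cells.update((f.query_id, p) for p in range(f.query_start, f.query_end))
    return cells


def oracle_adjacent_ok(prev, nxt, resolution, all_fragments):
    """Re-derivation of the pairwise chaining rule by per-base scanning."""
    if (prev.ref_id, prev.query_id, prev.strand) != (nxt.ref_id, nxt.query_id, nxt.strand):
        return False
    ref_gap = nxt.ref_start - prev.ref_end
    if not 0 <= ref_gap < resolution:
        return False
    if prev.strand == "+":
        q_lo, q_hi = prev.query_end, nxt.query_start
    else:
        q_lo, q_hi = nxt.query_end, prev.query_start
    if not 0 <= q_hi - q_lo < resolution:
        return False
    others = [f for f in all_fragments if f is not prev and f is not nxt]
    ref_cells = occupied(others, "ref")
    if any((prev.ref_id, p) in ref_cells for p in range(prev.ref_end, nxt.ref_start)):
        return False
    query_cells = occupied(others, "query")
    if any((prev.query_id, p) in query_cells for p in range(q_lo, q_hi)):
        return False
    return True


def oracle_chain(fragments, resolution):
    """Enumerate maximal valid contiguous runs over all subsequences.

    Within each (ref, query, strand) group sorted by reference start, every
    contiguous subsequence whose adjacent pairs all pass the chaining rule
    is a valid chain; the maximal ones that span >= resolution on both
    genomes are the expected CSBs.  Quadratic and per-base, deliberately
    unlike the production implementation.
    """
    groups = {}
    for f in fragments:
        groups.setdefault((f.ref_id, f.query_id, f.strand), []).append(f)
    expected = set()
    for key, group in groups.items():
        group.sort(key=lambda f: (f.ref_start, f.query_start))
        n = len(group)
        valid = [
            [
                all(
                    oracle_adjacent_ok(group[k], group[k + 1], resolution, fragments)
                    for k in range(i, j)
                )
                for j in range(n)
            ]
            for i in range(n)
        ]
        for i in range(n):
            for j in range(i, n):
                if not valid[i][j]:
                    continue
                left_ext = i > 0 and valid[i - 1][j]
                right_ext = j < n - 1 and valid[i][j + 1]
                if left_ext or right_ext:
                    continue  # not maximal
                chain = group[i : j + 1]
                ref_span = chain[-1].ref_end - chain[0].ref_start
                if key[2] == "+":
                    q_start, q_end = chain[0].query_start, chain[-1].query_end
                else:
                    q_start, q_end = chain[-1].query_start, chain[0].query_end
                if ref_span >= resolution and q_end - q_start >= resolution:
                    expected.add(
                        (key[0], chain[0].ref_start, chain[-1].ref_end,
                         key[1], q_start, q_end, key[2])
                    )
    return expected


def csb_keys(csb_set):
    return {
        (c.ref_id, c.ref_start, c.ref_end, c.query_id, c.query_start, c.query_end, c.strand)
        for c in csb_set
    }


def random_instance(rng, max_fragments=8):
    """A random overlap-resolved instance on up to 2 ref x 2 query sequences."""
    raw = []
    for _ in range(rng.randint(1, max_fragments)):
        ref_start = rng.randrange(0, 180)
        query_start = rng.randrange(0, 180)
        length = rng.randint(1, 40)
        raw.append(
            frag(
                ref_start,
                min(200, ref_start + length),
                query_start,
                min(200, query_start + rng.randint(1, 40)),
                rng.choice("+-"),
                score=rng.randint(1, 100),
                ref_id=rng.choice(["r1", "r2"]),
                query_id=rng.choice(["q1", "q2"]),
            )
        )
    return resolve_overlaps(aln_set(raw))


# --- resolve_overlaps ------------------------------------------------------


class TestResolveOverlaps:
    def test_disjoint_fragments_unchanged(self):
        fragments = [frag(0, 50, 0, 50), frag(100, 150, 100, 150)]
        result = resolve_overlaps(aln_set(fragments))
        assert sorted(result.fragments, key=lambda f: f.ref_start) == fragments

    def test_identical_duplicates_keep_one(self):
        f = frag(0, 50, 0, 50, score=10)
        result = resolve_overlaps(aln_set([f, f]))
        assert result.fragments == [f]

    def test_lower_score_trimmed_proportionally(self):
        # A (score 9) holds ref [0,100); B (score 5) enters at ref 70 with a
        # 130 bp ref / 130 bp query footprint: B loses 30 bp on the ref side
        # and 30 bp (same fraction) on the query side
        a = frag(0, 100, 0, 100, score=9)
        b = frag(70, 200, 200, 330, score=5)
        result = resolve_overlaps(aln_set([a, b]))
        by_score = sorted(result.fragments, key=lambda f: -f.score)
        assert by_score[0] == a
        trimmed = by_score[1]
        assert (trimmed.ref_start, trimmed.ref_end) == (100, 200)
        assert (trimmed.query_start, trimmed.query_end) == (230, 330)

    def test_minus_strand_trim_hits_opposite_query_end(self):
        a = frag(0, 100, 0, 100, score=9)
        # '-' fragment: trimming its ref START must trim its query END
        b = frag(80, 180, 300, 400, "-", score=5)
        result = resolve_overlaps(aln_set([a, b]))
        trimmed = [f for f in result.fragments if f.strand == "-"][0]
        assert (trimmed.ref_start, trimmed.ref_end) == (100, 180)
        assert (trimmed.query_start, trimmed.query_end) == (300, 380)

    @pytest.mark.parametrize("seed", range(40))
    def test_output_is_one_to_one_per_genome(self, seed):
        rng = random.Random(seed)
        result = random_instance(rng, max_fragments=5)
        for side in ("ref", "query"):
            seen = set()
            for f in result:
                cells = occupied([f], side)
                assert not cells & seen, f"{side} overlap after resolution"
                seen |= cells

    @pytest.mark.parametrize("seed", range(10))
    def test_top_score_fragment_never_trimmed(self, seed):
        rng = random.Random(1000 + seed)
        raw = []
        for _ in range(5):
            rs, qs = rng.randrange(150), rng.randrange(150)
            raw.append(frag(rs, rs + rng.randint(5, 40), qs, qs + rng.randint(5, 40),
                            score=rng.randint(1, 50)))
        winner = sorted(raw, key=lambda f: (-f.score, f.ref_id, f.ref_start,
                                            f.query_id, f.query_start))[0]
        result = resolve_overlaps(aln_set(raw))
        assert winner in result.fragments


# --- chain_fragments -------------------------------------------------------


class TestChainFragments:
    def test_single_fragment_chain(self):
        f = frag(0, 15_000, 0, 15_000)
        result = chain_fragments(aln_set([f]), 10_000)
        assert len(result) == 1
        csb = result.csbs[0]
        assert (csb.ref_start, csb.ref_end) == (0, 15_000)

    def test_small_gap_merges_and_combined_span_counts(self):
        # two 8 Kbp collinear fragments, 2 Kbp gap on both genomes: each
        # alone is under the 10 Kbp resolution, merged they span 18 Kbp
        fragments = [frag(0, 8000, 0, 8000), frag(10_000, 18_000, 10_000, 18_000)]
        result = chain_fragments(aln_set(fragments), 10_000)
        assert len(result) == 1
        csb = result.csbs[0]
        assert csb.ref_span == csb.query_span == 18_000
        assert len(csb.members) == 2

    def test_large_gap_splits_and_short_chains_are_discarded(self):
        fragments = [frag(0, 8000, 0, 8000), frag(20_000, 28_000, 20_000, 28_000)]
        result = chain_fragments(aln_set(fragments), 10_000)
        assert len(result) == 0

    def test_opposite_strands_never_chain(self):
        fragments = [frag(0, 12_000, 0, 12_000, "+"),
                     frag(13_000, 25_000, 30_000, 42_000, "-")]
        result = chain_fragments(aln_set(fragments), 10_000)
        assert len(result) == 2
        assert {c.strand for c in result} == {"+", "-"}

    def test_non_collinear_query_order_breaks_chain(self):
        # ref-adjacent but query jumps backwards on a '+' pair
        fragments = [frag(0, 12_000, 50_000, 62_000), frag(13_000, 25_000, 0, 12_000)]
        result = chain_fragments(aln_set(fragments), 10_000)
        assert len(result) == 2

    def test_occupied_gap_breaks_chain(self):
        # the 2 Kbp gap between the collinear '+' fragments holds a '-'
        # fragment on the reference: the run is not unaligned, no merge,
        # and each 8 Kbp piece then fails the 10 Kbp span test
        fragments = [
            frag(0, 8000, 0, 8000, "+"),
            frag(10_000, 18_000, 10_000, 18_000, "+"),
            frag(8500, 9500, 30_000, 31_000, "-", query_id="q2"),
        ]
        result = chain_fragments(aln_set(fragments), 10_000)
        assert csb_keys(result) == set()

    def test_resolution_below_one_rejected(self):
        with pytest.raises(ValueError):
            chain_fragments(aln_set([]), 0)

    @pytest.mark.parametrize("seed", range(250))
    def test_matches_brute_force_oracle(self, seed):
        rng = random.Random(seed)
        resolved = random_instance(rng)
        resolution = rng.choice([5, 10, 20, 40, 80])
        result = chain_fragments(resolved, resolution)
        assert csb_keys(result) == oracle_chain(resolved.fragments, resolution)

    @pytest.mark.parametrize("seed", range(30))
    def test_deterministic_under_input_shuffling(self, seed):
        rng = random.Random(seed)
        resolved = random_instance(rng)
        shuffled = list(resolved.fragments)
        rng.shuffle(shuffled)
        a = chain_fragments(resolved, 20)
        b = chain_fragments(AlignmentSet(resolved.reference, resolved.query, shuffled), 20)
        assert csb_keys(a) == csb_keys(b)


# --- build_csbs ------------------------------------------------------------


class TestBuildCsbs:
    def test_identity_pair_covers_fragments_end_to_end(self):
        ref = make_assembly("A", [40_000, 25_000])
        query = make_assembly("B", [40_000, 25_000])
        alignments = aln_set(
            [frag(0, 40_000, 0, 40_000, ref_id="s1", query_id="s1"),
             frag(0, 25_000, 0, 25_000, ref_id="s2", query_id="s2")]
        )
        result = build_csbs(ref, query, alignments, 10_000)
        assert result.count == 2
        assert result.ref_coverage_bp == result.query_coverage_bp == 65_000

    def test_empty_alignment_set(self):
        ref = make_assembly("A", [40_000])
        query = make_assembly("B", [40_000])
        result = build_csbs(ref, query, aln_set([]), 10_000)
        assert result.count == 0 and result.ref_coverage_bp == 0

    def test_alignments_on_short_fragments_excluded(self):
        # query fragment s2 (9 Kbp) is not strictly longer than the
        # resolution, so its alignment cannot seed a CSB
        ref = make_assembly("A", [40_000])
        query = make_assembly("B", [40_000, 9_000])
        alignments = aln_set(
            [frag(0, 9_000, 0, 9_000, ref_id="s1", query_id="s2"),
             frag(10_000, 40_000, 0, 30_000, ref_id="s1", query_id="s1")]
        )
        result = build_csbs(ref, query, alignments, 9_000)
        assert result.count == 1
        assert result.csbs[0].query_id == "s1"

    @pytest.mark.parametrize("seed", range(30))
    def test_coverage_and_count_bounds(self, seed):
        rng = random.Random(seed)
        ref = make_assembly("A", [200, 200], prefix="r")
        query = make_assembly("B", [200, 200], prefix="q")
        raw = []
        for _ in range(rng.randint(1, 8)):
            rs, qs = rng.randrange(150), rng.randrange(150)
            raw.append(frag(rs, rs + rng.randint(5, 50), qs, qs + rng.randint(5, 50),
                            rng.choice("+-"), score=rng.randint(1, 99),
                            ref_id=rng.choice(["r1", "r2"]),
                            query_id=rng.choice(["q1", "q2"])))
        resolution = rng.choice([10, 25, 60])
        result = build_csbs(ref, query, aln_set(raw), resolution)
        l_ref = filter_fragments(ref, resolution).total_length_bp
        l_query = filter_fragments(query, resolution).total_length_bp
        assert result.ref_coverage_bp <= l_ref
        assert result.query_coverage_bp <= l_query
        assert result.count <= l_ref // resolution
        assert result.count <= l_query // resolution
        for side in ("ref", "query"):
            seen = set()
            for c in result:
                if side == "ref":
                    cells = {(c.ref_id, p) for p in range(c.ref_start, c.ref_end)}
                else:
                    cells = {(c.query_id, p) for p in range(c.query_start, c.query_end)}
                assert not cells & seen, "CSB spans overlap"
                seen |= cells

    def test_monotone_in_resolution_for_gap_free_input(self):
        ref = make_assembly("A", [100_000])
        query = make_assembly("B", [100_000])
        alignments = aln_set(
            [frag(0, 30_000, 0, 30_000), frag(40_000, 90_000, 40_000, 90_000)]
        )
        counts = [
            build_csbs(ref, query, alignments, res).count
            for res in (5_000, 20_000, 35_000, 60_000)
        ]
        assert counts == sorted(counts, reverse=True)
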