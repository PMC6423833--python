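import pytest
from hypothesis import settings

from gmass import Assembly, AlignmentFragment, AlignmentSet, SequenceRecord

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_assembly(name, lengths, prefix="s"):
    """Assembly with fragments s1, s2, ... of the given lengths (no sequence)."""
    return Assembly(
        name, [SequenceRecord(f"{prefix}{k + 1}", length) for k, length in enumerate(lengths)]
    )


def frag(ref_start, ref_end, query_start, query_end, strand="+", score=None,
         ref_id="s1", query_id="s1"):
    if score is None:
        score = ref_end - ref_start
    return AlignmentFragment(
        ref_id=ref_id,
        ref_start=ref_start,
        ref_end=ref_end,
        query_id=query_id,
        query_start=query_start,
        query_end=query_end,
        strand=strand,
        score=score,
    )


def aln_set(fragments, reference="A", query="B"):
    return AlignmentSet(reference=reference, query=query, fragments=list(fragments))


@pytest.fixture
def five_lengths_assembly():
    """The {8, 7, 5, 3, 2} toy used for Nx checks (total 25)."""
    return make_assembly("toy", [8, 7, 5, 3, 2])
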