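"""Region merging, length splitting, redundancy filtering and summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from disquad import regions as reg
from disquad.readers import Cluster
from disquad.types import AnnotatedRegion, ProteinRecord


def region(acc, start, end, terms=("IDPO:00076",), source=None):
    return AnnotatedRegion(
        accession=acc, start=start, end=end,
        structural_state_terms=frozenset(terms),
        source_ids=frozenset({source or f"{acc}_{start}_{end}"}),
    )


# ------------------------------------------------------------------ merging

def covered_positions(regions):
    """Brute-force oracle: the exact set of (accession, position) pairs."""
    return {(r.accession, p) for r in regions for p in r.positions()}


def test_merge_unions_overlapping_intervals():
    merged = reg.merge_overlapping([region("P1", 1, 10), region("P1", 5, 20)])
    assert [(r.start, r.end) for r in merged] == [(1, 20)]
    assert merged[0].source_ids == {"P1_1_10", "P1_5_20"}


def test_merge_keeps_adjacent_intervals_separate():
    merged = reg.merge_overlapping([region("P1", 1, 10), region("P1", 11, 20)])
    assert [(r.start, r.end) for r in merged] == [(1, 10), (11, 20)]


def test_merge_single_region_unchanged():
    r = region("P1", 3, 9)
    assert reg.merge_overlapping([r]) == [r]


def test_merge_unions_term_sets():
    a = AnnotatedRegion("P1", 1, 10, structural_state_terms=frozenset({"IDPO:00076"}),
                        evidence_terms=frozenset({"ECO:0006220"}),
                        source_ids=frozenset({"a"}))
    b = AnnotatedRegion("P1", 8, 15, evidence_terms=frozenset({"ECO:0006165"}),
                        function_terms=frozenset({"GO:0005515"}),
                        source_ids=frozenset({"b"}))
    (m,) = reg.merge_overlapping([a, b])
    assert m.evidence_terms == {"ECO:0006220", "ECO:0006165"}
    assert m.function_terms == {"GO:0005515"}
    assert m.source_ids == {"a", "b"}


interval_lists = st.lists(
    st.tuples(
        st.sampled_from(["A", "B"]),
        st.integers(min_value=1, max_value=60),
        st.integers(min_value=0, max_value=25),
    ),
    min_size=0,
    max_size=12,
)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(interval_lists)
def test_merge_preserves_position_set(raw):
    """Merged output covers exactly the same positions as the input."""
    regions = [region(acc, start, start + span) for acc, start, span in raw]
    merged = reg.merge_overlapping(regions)
    assert covered_positions(merged) == covered_positions(regions)
    # no two output regions on one accession overlap
    by_acc = {}
    for r in merged:
        by_acc.setdefault(r.accession, []).append(r)
    for rs in by_acc.values():
        rs.sort(key=lambda r: r.start)
        for a, b in zip(rs, rs[1:]):
            assert a.end < b.start


@settings(max_examples=100, deadline=None, derandomize=True)
@given(interval_lists)
def test_merge_is_idempotent(raw):
    regions = [region(acc, start, start + span) for acc, start, span in raw]
    merged = reg.merge_overlapping(regions)
    assert reg.merge_overlapping(merged) == merged


# ------------------------------------------------------------------ splitting

@pytest.mark.parametrize(
    "length,expect_long", [(30, True), (29, False), (31, True), (1, False)]
)
def test_split_by_length_boundary(length, expect_long):
    r = region("P1", 1, length)
    long_r, short_r = reg.split_by_length([r], min_long=30)
    assert (len(long_r) == 1) is expect_long
    assert (len(short_r) == 1) is not expect_long


def test_split_empty_input():
    assert reg.split_by_length([]) == ([], [])


@settings(max_examples=100, deadline=None, derandomize=True)
@given(interval_lists, st.integers(min_value=1, max_value=40))
def test_split_partitions_exhaustively(raw, min_long):
    regions = [region(acc, start, start + span) for acc, start, span in raw]
    long_r, short_r = reg.split_by_length(regions, min_long)
    assert len(long_r) + len(short_r) == len(regions)
    assert sum(r.length for r in long_r) + sum(r.length for r in short_r) == sum(
        r.length for r in regions
    )
    assert all(r.length >= min_long for r in long_r)
    assert all(r.length < min_long for r in short_r)


# ------------------------------------------------------------------ redundancy

def test_identical_sequences_collapse():
    proteins = [ProteinRecord("P1", "MKLV" * 10), ProteinRecord("P2", "MKLV" * 10)]
    kept = reg.apply_redundancy_filter(proteins, None, 0.40)
    assert len(kept) == 1


def test_clstr_representatives_kept():
    proteins = [ProteinRecord(a, "MKLV") for a in ("P1", "P2", "P3")]
    clusters = [Cluster(("P1", "P2"), "P1"), Cluster(("P3",), "P3")]
    kept = reg.apply_redundancy_filter(proteins, clusters)
    assert [p.accession for p in kept] == ["P1", "P3"]


def test_clstr_unknown_id_rejected():
    proteins = [ProteinRecord("P1", "MKLV")]
    clusters = [Cluster(("P1", "PX"), "P1")]
    with pytest.raises(ValueError, match="PX"):
        reg.apply_redundancy_filter(proteins, clusters)


def test_unrelated_sequences_both_kept():
    rng = np.random.default_rng(11)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    a = "".join(rng.choice(alphabet, size=50))
    b = "".join(rng.choice(alphabet, size=50))
    # exhaustive position-by-position identity, the definition itself
    identity = sum(1 for x, y in zip(a, b) if x == y) / 50
    assert identity < 0.40  # random 20-letter sequences sit near 5%
    kept = reg.apply_redundancy_filter(
        [ProteinRecord("P1", a), ProteinRecord("P2", b)], None, 0.40
    )
    assert len(kept) == 2


# ------------------------------------------------------------------ summaries

def test_summarize_counts():
    rs = [region("P1", 1, 10), region("P1", 21, 25)]
    s = reg.summarize(rs)
    assert (s.n_regions, s.n_residues, s.n_proteins) == (2, 15, 1)


def test_summarize_empty():
    s = reg.summarize([])
    assert (s.n_regions, s.n_residues, s.n_proteins) == (0, 0, 0)


def test_summarize_two_proteins():
    rs = [region("P1", 1, 30), region("P2", 1, 30)]
    s = reg.summarize(rs)
    assert (s.n_regions, s.n_residues, s.n_proteins) == (2, 60, 2)
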