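"""Cutoff semantics, quadrant classification, matched-rate calibration,
apportioned percentage tables and density grids."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from disquad import quadrants as quad
from disquad.types import AnnotatedRegion, CutoffPair, ScoreTrack

CUTOFFS = CutoffPair()  # pLDDT 0.7 / IUPred 0.425


# ------------------------------------------------------------------ cutoffs

@pytest.mark.parametrize(
    "score,predictor,expected",
    [
        (0.69, "plddt", True),
        (0.70, "plddt", False),
        (0.425, "iupred", False),
        (0.426, "iupred", True),
        (0.0, "plddt", True),
        (1.0, "iupred", True),
        (0.0, "iupred", False),
    ],
)
def test_is_disordered_strict_inequalities(score, predictor, expected):
    assert quad.is_disordered(score, predictor, CUTOFFS) is expected


@pytest.mark.parametrize(
    "iupred,plddt,expected",
    [
        (0.8, 0.3, "Q4"),
        (0.2, 0.9, "Q1"),
        (0.6, 0.9, "Q2"),
        (0.2, 0.4, "Q3"),
    ],
)
def test_classify_residue_quadrants(iupred, plddt, expected):
    assert quad.classify_residue(iupred, plddt, CUTOFFS) == expected


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.floats(min_value=0, max_value=1, allow_nan=False),
    st.floats(min_value=0, max_value=1, allow_nan=False),
)
def test_classify_matches_truth_table(iupred, plddt):
    """Quadrant equals the truth-table combination of the two binary calls."""
    dis_i = quad.is_disordered(iupred, "iupred", CUTOFFS)
    dis_p = quad.is_disordered(plddt, "plddt", CUTOFFS)
    truth = {
        (False, False): "Q1",
        (True, False): "Q2",
        (False, True): "Q3",
        (True, True): "Q4",
    }[(dis_i, dis_p)]
    assert quad.classify_residue(iupred, plddt, CUTOFFS) == truth
    assert quad.classify_residues(np.array([iupred]), np.array([plddt]), CUTOFFS)[0] == truth


# ------------------------------------------------------------------ calibration

def brute_force_cutoff(scores, target):
    """Independent oracle: scan every candidate cutoff by direct counting."""
    candidates = sorted(set(scores) | {0.0})
    n = len(scores)
    for c in candidates:
        above = sum(1 for s in scores if s > c)
        if above / n <= target:
            return c, above / n
    raise AssertionError("unreachable: max(scores) always qualifies")


def test_calibrate_matched_cutoff_decile_example():
    scores = [i / 10 for i in range(1, 11)]
    result = quad.calibrate_matched_cutoff(scores, 0.3)
    assert result.cutoff == pytest.approx(0.7)
    assert result.achieved_fraction == pytest.approx(0.3)


def test_calibrate_target_zero_returns_max():
    assert quad.calibrate_matched_cutoff([0.2, 0.9, 0.5], 0.0).cutoff == pytest.approx(0.9)


def test_calibrate_degenerate_equal_scores():
    result = quad.calibrate_matched_cutoff([0.5] * 7, 0.5)
    assert result.cutoff == pytest.approx(0.5)
    assert result.achieved_fraction == 0.0


def test_calibrate_empty_rejected():
    with pytest.raises(ValueError):
        quad.calibrate_matched_cutoff([], 0.5)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    st.lists(
        st.floats(min_value=0, max_value=1, allow_nan=False, width=32),
        min_size=1, max_size=200,
    ),
    st.floats(min_value=0, max_value=1, allow_nan=False),
)
def test_calibrate_equals_brute_force(scores, target):
    expect_cutoff, expect_frac = brute_force_cutoff(scores, target)
    result = quad.calibrate_matched_cutoff(scores, target)
    assert result.cutoff == pytest.approx(expect_cutoff)
    assert result.achieved_fraction == pytest.approx(expect_frac)
    # round trip: applying the calibrated cutoff never exceeds the target
    assert result.achieved_fraction <= target + 1e-12


@pytest.mark.parametrize(
    "scores,cutoff,expected",
    [
        ([0.6, 0.8], 0.7, 0.5),
        ([0.9, 0.95], 0.7, 0.0),
        ([0.7], 0.7, 0.0),
    ],
)
def test_target_fraction_from_plddt(scores, cutoff, expected):
    assert quad.target_fraction_from_plddt(scores, cutoff) == pytest.approx(expected)


# ------------------------------------------------------------------ region means

def make_tracks(iupred, plddt):
    return (
        ScoreTrack("P1", "iupred", np.asarray(iupred)),
        ScoreTrack("P1", "plddt", np.asarray(plddt)),
    )


def test_region_mean_quadrant_hand_arithmetic():
    iup, pld = make_tracks([0.5, 0.5, 0.2], [0.8, 0.6, 0.4])
    region = AnnotatedRegion("P1", 1, 3)
    mean_i, mean_p, q = quad.region_mean_quadrant(region, iup, pld, CUTOFFS)
    assert mean_i == pytest.approx(0.4)
    assert mean_p == pytest.approx(0.6)
    assert q == "Q3"


def test_region_mean_quadrant_constant_tracks():
    iup, pld = make_tracks([0.9] * 5, [0.1] * 5)
    _, _, q = quad.region_mean_quadrant(AnnotatedRegion("P1", 2, 4), iup, pld, CUTOFFS)
    assert q == "Q4"


def test_region_mean_single_residue():
    iup, pld = make_tracks([0.1, 0.8, 0.1], [0.9, 0.2, 0.9])
    mean_i, mean_p, q = quad.region_mean_quadrant(AnnotatedRegion("P1", 2, 2), iup, pld, CUTOFFS)
    assert (mean_i, mean_p, q) == (0.8, 0.2, "Q4")


def test_region_outside_track_rejected():
    iup, pld = make_tracks([0.5] * 3, [0.5] * 3)
    with pytest.raises(ValueError, match="extends past"):
        quad.region_mean_quadrant(AnnotatedRegion("P1", 2, 5), iup, pld, CUTOFFS)


# ------------------------------------------------------------------ tables

def table_from_counts(counts):
    labels = [q for q, n in counts.items() for _ in range(n)]
    return quad.quadrant_table(labels)


def test_quadrant_table_symmetry():
    t = table_from_counts({"Q1": 1, "Q2": 1, "Q3": 1, "Q4": 1})
    assert t.percentages == {"Q1": 25, "Q2": 25, "Q3": 25, "Q4": 25}


def test_quadrant_table_empty():
    t = quad.quadrant_table([])
    assert t.total == 0 and t.percentages == {}


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.fixed_dictionaries(
        {q: st.integers(min_value=0, max_value=10_000) for q in ("Q1", "Q2", "Q3", "Q4")}
    )
)
def test_apportionment_sums_to_100_and_is_close(counts):
    total = sum(counts.values())
    pct = quad.largest_remainder_percentages(counts)
    if total == 0:
        assert pct == {}
        return
    assert sum(pct.values()) == 100
    for q, n in counts.items():
        assert abs(pct[q] - 100 * n / total) < 1.0


# ------------------------------------------------------------------ grids

def test_density_grid_point_mass():
    grid = quad.density_grid([(0.5, 0.5)] * 9, bins=50)
    assert grid.matrix.sum() == 9
    assert grid.matrix.max() == 9


def test_density_grid_upper_edge_closed():
    grid = quad.density_grid([(1.0, 1.0)], bins=10)
    assert grid.matrix[-1, -1] == 1


def test_density_grid_corners_enumeration():
    pairs = [(0.0, 0.0), (0.0, 1.0), (1.0, 0.0), (1.0, 1.0)]
    grid = quad.density_grid(pairs, bins=2)
    assert grid.matrix.sum() == 4
    assert (grid.matrix == 1).all()


def test_density_grid_rejects_bad_bins():
    with pytest.raises(ValueError):
        quad.density_grid([(0.5, 0.5)], bins=0)
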