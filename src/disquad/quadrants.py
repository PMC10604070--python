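"""Quadrant classification of predictor agreement, matched-rate cutoff
calibration, quadrant count tables and 2D score histograms.

The joint classification places each residue (or region, via its mean
scores) in one of four quadrants:

* **Q1** — both predictors call order (pLDDT high, IUPred low);
* **Q2** — pLDDT calls order, IUPred calls disorder;
* **Q3** — pLDDT calls disorder, IUPred calls order;
* **Q4** — both call disorder.

On a set of experimentally annotated disordered residues, Q4 is agreement
with the annotation, Q1 is joint contradiction, Q2/Q3 are one-sided
disagreements.

Disorder calls use strict inequalities: pLDDT *below* its cutoff and
IUPred *above* its cutoff are disordered; residues exactly at a cutoff are
called ordered.  The IUPred cutoff is typically calibrated so both
predictors label the same overall fraction of residues disordered
(:func:`calibrate_matched_cutoff`), which makes the two one-sided
disagreement quadrants directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .types import QUADRANTS, AnnotatedRegion, CutoffPair, ScoreTrack


def is_disordered(score: float, predictor: str, cutoffs: CutoffPair) -> bool:
    """Whether one predictor's score is a disorder call.

    pLDDT: disordered iff ``score < plddt_cutoff`` (low model confidence);
    IUPred: disordered iff ``score > iupred_cutoff``.  Both strict.
    """
    if predictor == "plddt":
        return score < cutoffs.plddt_cutoff
    if predictor == "iupred":
        return score > cutoffs.iupred_cutoff
    raise ValueError(f"unknown predictor {predictor!r}")


def classify_residue(iupred: float, plddt: float, cutoffs: CutoffPair) -> str:
    """Quadrant of a single residue from its two scores."""
    dis_iupred = is_disordered(iupred, "iupred", cutoffs)
    dis_plddt = is_disordered(plddt, "plddt", cutoffs)
    if dis_plddt:
        return "Q4" if dis_iupred else "Q3"
    return "Q2" if dis_iupred else "Q1"


def classify_residues(
    iupred: np.ndarray, plddt: np.ndarray, cutoffs: CutoffPair
) -> np.ndarray:
    """Vectorized :func:`classify_residue` over parallel score arrays."""
    iupred = np.asarray(iupred, dtype=float)
    plddt = np.asarray(plddt, dtype=float)
    if iupred.shape != plddt.shape:
        raise ValueError("score arrays must have identical shapes")
    dis_i = iupred > cutoffs.iupred_cutoff
    dis_p = plddt < cutoffs.plddt_cutoff
    out = np.where(
        dis_p,
        np.where(dis_i, "Q4", "Q3"),
        np.where(dis_i, "Q2", "Q1"),
    )
    return out


class CalibrationResult(NamedTuple):
    """A calibrated cutoff and the disorder fraction it achieves."""

    cutoff: float
    achieved_fraction: float


def target_fraction_from_plddt(
    plddt_scores: Sequence[float], plddt_cutoff: float = 0.7
) -> float:
    """Fraction of scores strictly below the pLDDT cutoff (disorder rate)."""
    arr = np.asarray(plddt_scores, dtype=float)
    if arr.size == 0:
        raise ValueError("empty score set")
    return float(np.count_nonzero(arr < plddt_cutoff) / arr.size)


def calibrate_matched_cutoff(
    iupred_scores: Sequence[float], target_fraction: float
) -> CalibrationResult:
    """Pick the IUPred cutoff whose disorder rate matches a target.

    Candidates are the observed score values plus 0 (deterministic and
    data-driven, no arbitrary grid).  Returns the smallest candidate ``c``
    such that the fraction of scores strictly greater than ``c`` is at most
    ``target_fraction``, together with that achieved fraction.
    """
    arr = np.sort(np.asarray(iupred_scores, dtype=float))
    if arr.size == 0:
        raise ValueError("empty score set")
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError(f"target_fraction must be in [0, 1], got {target_fraction}")
    n = arr.size
    candidates = np.unique(np.concatenate(([0.0], arr)))
    # fraction strictly greater than c, for every candidate at once
    above = n - np.searchsorted(arr, candidates, side="right")
    fractions = above / n
    ok = np.nonzero(fractions <= target_fraction)[0]
    idx = int(ok[0])  # candidates ascending -> first hit is the smallest
    return CalibrationResult(
        cutoff=float(candidates[idx]), achieved_fraction=float(fractions[idx])
    )


def region_mean_quadrant(
    region: AnnotatedRegion,
    iupred: ScoreTrack,
    plddt: ScoreTrack,
    cutoffs: CutoffPair,
) -> tuple[float, float, str]:
    """Mean scores over a region and the quadrant of those means.

    Region coordinates are 1-based inclusive; both tracks must cover the
    full interval.
    """
    if region.end > len(iupred) or region.end > len(plddt):
        raise ValueError(
            f"region {region.accession}:{region.start}-{region.end} extends "
            f"past track length (iupred {len(iupred)}, plddt {len(plddt)})"
        )
    sl = slice(region.start - 1, region.end)
    mean_iupred = float(np.mean(iupred.scores[sl]))
    mean_plddt = float(np.mean(plddt.scores[sl]))
    return mean_iupred, mean_plddt, classify_residue(mean_iupred, mean_plddt, cutoffs)


@dataclass(frozen=True)
class QuadrantTable:
    """Counts and integer percentages of items per quadrant.

    Percentages come from largest-remainder (Hamilton) apportionment of
    ``100 * count / total`` so the four printed integers always sum to
    exactly 100 (plain rounding does not guarantee this).
    """

    counts: dict[str, int]
    percentages: dict[str, int]
    total: int
    unit: str


def largest_remainder_percentages(counts: dict[str, int]) -> dict[str, int]:
    """Integer percentages summing to 100 by largest-remainder apportionment.

    Each key gets the floor of its exact percentage; the leftover points are
    handed out in order of decreasing fractional remainder (ties broken by
    larger count, then key order, for determinism).
    """
    total = sum(counts.values())
    if total == 0:
        return {}
    exact = {k: 100.0 * c / total for k, c in counts.items()}
    floors = {k: int(v) for k, v in exact.items()}
    leftover = 100 - sum(floors.values())
    order = sorted(
        counts,
        key=lambda k: (-(exact[k] - floors[k]), -counts[k], k),
    )
    out = dict(floors)
    for k in order[:leftover]:
        out[k] += 1
    return out


def quadrant_table(
    quadrant_labels: Iterable[str], unit: str = "residues"
) -> QuadrantTable:
    """Tally quadrant labels into counts and apportioned percentages."""
    counts = {q: 0 for q in QUADRANTS}
    total = 0
    for q in quadrant_labels:
        if q not in counts:
            raise ValueError(f"unknown quadrant label {q!r}")
        counts[q] += 1
        total += 1
    return QuadrantTable(
        counts=counts,
        percentages=largest_remainder_percentages(counts) if total else {},
        total=total,
        unit=unit,
    )


@dataclass(frozen=True)
class DensityGrid:
    """2D histogram of (IUPred, pLDDT) score pairs.

    ``matrix[i, j]`` counts pairs whose pLDDT falls in x-bin ``i`` and
    IUPred in y-bin ``j``; bins are uniform half-open ``[lo, hi)`` over
    [0, 1] except the last, which is closed so 1.0 is binned.
    """

    bins: int
    matrix: np.ndarray
    x_axis: str = "plddt"
    y_axis: str = "iupred"


def density_grid(
    pairs: Iterable[tuple[float, float]], bins: int = 50
) -> DensityGrid:
    """Bin (iupred, plddt) score pairs on a uniform grid over [0, 1]^2."""
    if bins < 1:
        raise ValueError(f"bins must be >= 1, got {bins}")
    arr = np.asarray(list(pairs), dtype=float).reshape(-1, 2)
    if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
        raise ValueError("scores outside [0, 1]")
    edges = np.linspace(0.0, 1.0, bins + 1)
    matrix, _, _ = np.histogram2d(arr[:, 1], arr[:, 0], bins=(edges, edges))
    return DensityGrid(bins=bins, matrix=matrix.astype(int))
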