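"""Proteome-scale disordered-residue fractions per predictor.

For whole proteomes (no experimental annotation), each predictor's
disordered fraction is the residue-pooled rate over all proteins — the
number of disorder-called residues divided by the total residue count, not
an average of per-protein fractions — using the same cutoffs as the
annotation-level analyses.  Proteomes are then rolled up by taxonomic
division (Eukaryota / Bacteria / Archaea) with residue weighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import CutoffPair, ScoreTrack

DIVISIONS = ("Eukaryota", "Bacteria", "Archaea")


@dataclass(frozen=True)
class ProteomeSummary:
    """Pooled disorder fractions for one proteome."""

    proteome_id: str
    division: str
    n_residues: int
    disordered_fraction_plddt: float
    disordered_fraction_iupred: float

    def __post_init__(self) -> None:
        if self.division not in DIVISIONS:
            raise ValueError(f"unknown division {self.division!r}")


def proteome_fractions(
    tracks: list[tuple[ScoreTrack, ScoreTrack]],
    cutoffs: CutoffPair,
) -> tuple[float, float, int]:
    """Residue-pooled disordered fractions over paired score tracks.

    ``tracks`` holds one (iupred, plddt) pair per protein; the two tracks
    of a pair must be equally long.  Returns (fraction_iupred,
    fraction_plddt, n_residues).
    """
    n_total = 0
    n_dis_iupred = 0
    n_dis_plddt = 0
    for iupred, plddt in tracks:
        if iupred.predictor != "iupred" or plddt.predictor != "plddt":
            raise ValueError("tracks must be ordered (iupred, plddt) per pair")
        if len(iupred) != len(plddt):
            raise ValueError(
                f"{iupred.accession}: track lengths differ "
                f"({len(iupred)} vs {len(plddt)})"
            )
        n_total += len(iupred)
        n_dis_iupred += int(np.count_nonzero(iupred.scores > cutoffs.iupred_cutoff))
        n_dis_plddt += int(np.count_nonzero(plddt.scores < cutoffs.plddt_cutoff))
    if n_total == 0:
        raise ValueError("no residues in input")
    return n_dis_iupred / n_total, n_dis_plddt / n_total, n_total


def summarize_proteome(
    proteome_id: str,
    division: str,
    tracks: list[tuple[ScoreTrack, ScoreTrack]],
    cutoffs: CutoffPair,
) -> ProteomeSummary:
    """Convenience wrapper building a :class:`ProteomeSummary`."""
    f_iupred, f_plddt, n = proteome_fractions(tracks, cutoffs)
    return ProteomeSummary(
        proteome_id=proteome_id,
        division=division,
        n_residues=n,
        disordered_fraction_plddt=f_plddt,
        disordered_fraction_iupred=f_iupred,
    )


def divisions_summary(
    summaries: list[ProteomeSummary],
) -> dict[str, dict[str, float]]:
    """Residue-weighted pooled fractions per division.

    Returns division -> {"n_residues", "fraction_plddt", "fraction_iupred",
    "mean_fraction_plddt", "mean_fraction_iupred", "n_proteomes"}; the
    ``mean_*`` entries are unweighted per-proteome averages, emitted for
    transparency alongside the pooled values.
    """
    out: dict[str, dict[str, float]] = {}
    for division in DIVISIONS:
        members = [s for s in summaries if s.division == division]
        if not members:
            continue
        n = sum(s.n_residues for s in members)
        pooled_p = sum(s.disordered_fraction_plddt * s.n_residues for s in members) / n
        pooled_i = sum(s.disordered_fraction_iupred * s.n_residues for s in members) / n
        out[division] = {
            "n_residues": n,
            "n_proteomes": len(members),
            "fraction_plddt": pooled_p,
            "fraction_iupred": pooled_i,
            "mean_fraction_plddt": float(
                np.mean([s.disordered_fraction_plddt for s in members])
            ),
            "mean_fraction_iupred": float(
                np.mean([s.disordered_fraction_iupred for s in members])
            ),
        }
    return out
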