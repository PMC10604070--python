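"""Core domain types shared across the pipeline.

Coordinate convention
---------------------
All intervals are **1-based and inclusive** (the DisProt convention): a
region ``(start=5, end=12)`` covers residues 5, 6, ..., 12 and has length
``end - start + 1 = 8``.  Score tracks and secondary-structure strings are
indexed so that residue ``i`` lives at Python index ``i - 1``.

Score convention
----------------
Both predictor tracks live on the ``[0, 1]`` scale.  IUPred natively emits
scores in ``[0, 1]`` where *higher* means more disordered; AlphaFold pLDDT
values (0-100, higher means more confident, i.e. more ordered) are divided
by 100 at read time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Valid predictor identifiers.
PREDICTORS = ("iupred", "plddt")

#: Quadrant labels for the joint order/disorder classification.
QUADRANTS = ("Q1", "Q2", "Q3", "Q4")

#: Taxonomic depth tiers, ordered shallow -> deep.
CONSERVATION_LEVELS = ("Vertebrata", "Eumetazoa", "Unicellular")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a unique accession."""

    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.accession}: sequence must be non-empty")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ScoreTrack:
    """Per-residue scores on [0, 1] for one protein and one predictor.

    ``scores[i]`` is the score of residue ``i + 1``.
    """

    accession: str
    predictor: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        if self.predictor not in PREDICTORS:
            raise ValueError(f"unknown predictor {self.predictor!r}")
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1:
            raise ValueError("scores must be one-dimensional")
        if self.scores.size and (self.scores.min() < 0.0 or self.scores.max() > 1.0):
            raise ValueError(
                f"{self.accession}/{self.predictor}: scores outside [0, 1]"
            )

    def __len__(self) -> int:
        return int(self.scores.size)


@dataclass(frozen=True)
class AnnotatedRegion:
    """A 1-based inclusive interval carrying ontology term annotations.

    Term identifiers are partitioned into four categories:

    * ``structural_state_terms`` — disorder flavour terms (disorder, molten
      globule, pre-molten globule, ...).
    * ``transition_terms`` — structural-transition terms (disorder-to-order,
      order-to-disorder, ...).
    * ``function_terms`` — functional terms (protein binding, flexible
      linker, ...).
    * ``evidence_terms`` — ECO experimental-evidence identifiers.

    ``source_ids`` records the entry/region identifiers that contributed to
    this (possibly merged) region.
    """

    accession: str
    start: int
    end: int
    structural_state_terms: frozenset[str] = frozenset()
    transition_terms: frozenset[str] = frozenset()
    function_terms: frozenset[str] = frozenset()
    evidence_terms: frozenset[str] = frozenset()
    source_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.accession}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"{self.accession}: end ({self.end}) < start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def all_terms(self) -> frozenset[str]:
        return (
            self.structural_state_terms
            | self.transition_terms
            | self.function_terms
            | self.evidence_terms
        )

    def positions(self) -> range:
        """All residue positions covered, as 1-based integers."""
        return range(self.start, self.end + 1)


@dataclass(frozen=True)
class SSString:
    """Per-residue 8-state DSSP assignment for one protein.

    ``states8[i]`` is the DSSP single-letter code of residue ``i + 1``;
    unassigned residues (chain breaks, blanks) are stored as ``-``.
    """

    accession: str
    states8: str


@dataclass(frozen=True)
class MSARow:
    """One aligned sequence in an ortholog alignment."""

    ortholog_id: str
    level: str
    sequence: str

    def __post_init__(self) -> None:
        if self.level not in CONSERVATION_LEVELS:
            raise ValueError(
                f"{self.ortholog_id}: level must be one of {CONSERVATION_LEVELS}, "
                f"got {self.level!r}"
            )


@dataclass
class OrthologAlignment:
    """A region-restricted multiple sequence alignment of orthologs.

    ``reference_row`` indexes the annotated protein's own row.  ``ref_start``
    is the protein position (1-based) of the reference row's first residue,
    so a region-restricted alignment of residues 40-80 has ``ref_start=40``.
    """

    region_id: str
    rows: list[MSARow]
    reference_row: int
    ref_start: int = 1

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError(f"{self.region_id}: alignment has no rows")
        widths = {len(r.sequence) for r in self.rows}
        if len(widths) != 1:
            raise ValueError(
                f"{self.region_id}: rows have unequal aligned lengths {sorted(widths)}"
            )
        if not 0 <= self.reference_row < len(self.rows):
            raise ValueError(f"{self.region_id}: reference_row out of range")

    @property
    def width(self) -> int:
        return len(self.rows[0].sequence)

    @property
    def reference(self) -> MSARow:
        return self.rows[self.reference_row]


@dataclass(frozen=True)
class CutoffPair:
    """Decision thresholds for the two predictors.

    A residue is called disordered when its pLDDT score is strictly below
    ``plddt_cutoff`` or its IUPred score is strictly above ``iupred_cutoff``.
    Defaults are the conventional 0.7 (pLDDT, on the 0-1 scale) and the
    matched-rate IUPred value 0.425.
    """

    plddt_cutoff: float = 0.7
    iupred_cutoff: float = 0.425

    def __post_init__(self) -> None:
        for name, v in (("plddt_cutoff", self.plddt_cutoff),
                        ("iupred_cutoff", self.iupred_cutoff)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def as_frozenset(terms: Sequence[str] | frozenset[str] | None) -> frozenset[str]:
    """Normalize an optional term collection to a frozenset."""
    if terms is None:
        return frozenset()
    return frozenset(terms)
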