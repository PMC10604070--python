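"""Evolutionary conservation depth of annotated regions from ortholog MSAs.

Each ortholog in a region alignment is tagged with one of three taxonomic
tiers — Vertebrata (shallowest), Eumetazoa, Unicellular (deepest ancestry).
A region is called conserved at a tier when at least ``min_orthologs``
(default 3) orthologs of that tier align to it; the region's conservation
level is the deepest tier that qualifies.  An ortholog "aligns" to the
region when at least ``min_coverage`` (default 50%) of the region's
alignment columns are non-gap in its row — mere presence in the alignment
file is not enough, all-gap rows never count.
"""

from __future__ import annotations

from dataclasses import dataclass

from .types import CONSERVATION_LEVELS, AnnotatedRegion, OrthologAlignment

#: outcome when no tier reaches the ortholog minimum
UNCLASSIFIED = "unclassified"

#: tiers ordered deepest ancestry first
_DEPTH_ORDER = tuple(reversed(CONSERVATION_LEVELS))  # Unicellular, Eumetazoa, Vertebrata

_GAPS = frozenset("-.")


@dataclass(frozen=True)
class ConservationCall:
    """A region's conservation depth and the per-tier ortholog counts."""

    region_id: str
    level: str  # one of CONSERVATION_LEVELS or "unclassified"
    counts: dict[str, int]


def region_columns(
    alignment: OrthologAlignment, region: AnnotatedRegion
) -> range:
    """Alignment columns (0-based, half-open) covering the region.

    The region's 1-based protein coordinates are mapped onto the reference
    row by walking its residues and skipping gap columns; ``ref_start``
    anchors region-restricted alignments whose reference row starts
    mid-protein.
    """
    ref = alignment.reference.sequence
    first_ordinal = region.start - alignment.ref_start + 1
    last_ordinal = region.end - alignment.ref_start + 1
    if first_ordinal < 1:
        raise ValueError(
            f"{alignment.region_id}: region starts before the reference row"
        )
    start_col = end_col = None
    ordinal = 0
    for col, ch in enumerate(ref):
        if ch in _GAPS:
            continue
        ordinal += 1
        if ordinal == first_ordinal:
            start_col = col
        if ordinal == last_ordinal:
            end_col = col
            break
    if start_col is None or end_col is None:
        raise ValueError(
            f"{alignment.region_id}: region {region.start}-{region.end} extends "
            f"past the reference sequence ({ordinal} residues)"
        )
    return range(start_col, end_col + 1)


def classify_conservation(
    alignment: OrthologAlignment,
    region: AnnotatedRegion,
    min_orthologs: int = 3,
    min_coverage: float = 0.5,
) -> ConservationCall:
    """Deepest taxonomic tier with enough aligned orthologs over a region.

    With ``min_coverage=0`` every row with at least one non-gap character in
    the region counts; with ``min_coverage=1`` only rows covering every
    region column count.
    """
    if not 0.0 <= min_coverage <= 1.0:
        raise ValueError(f"min_coverage must be in [0, 1], got {min_coverage}")
    cols = region_columns(alignment, region)
    n_cols = len(cols)
    counts = {level: 0 for level in CONSERVATION_LEVELS}
    for i, row in enumerate(alignment.rows):
        if i == alignment.reference_row:
            continue
        non_gap = sum(1 for c in cols if row.sequence[c] not in _GAPS)
        if n_cols == 0:
            continue
        covered = (
            non_gap / n_cols >= min_coverage if min_coverage > 0 else non_gap > 0
        )
        if covered:
            counts[row.level] += 1
    level = UNCLASSIFIED
    for tier in _DEPTH_ORDER:
        if counts[tier] >= min_orthologs:
            level = tier
            break
    return ConservationCall(region_id=alignment.region_id, level=level, counts=counts)
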