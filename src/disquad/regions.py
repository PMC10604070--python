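"""Region-set operations: overlap merging, length splitting, redundancy
filtering and summaries.

Curated disorder annotations frequently overlap (the same stretch may be
annotated from several papers or by several methods), so residue-level
statistics use the merged, non-overlapping region set while term-level
statistics count the pre-merge entries.  "Overlap" means sharing at least
one residue position; adjacent intervals are kept separate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby

from .readers import Cluster
from .types import AnnotatedRegion, ProteinRecord


@dataclass(frozen=True)
class RegionSetSummary:
    """Counts for a set of annotated regions."""

    n_regions: int
    n_residues: int
    n_proteins: int


def merge_overlapping(regions: list[AnnotatedRegion]) -> list[AnnotatedRegion]:
    """Merge regions that share at least one position, per accession.

    Each merged region is the union interval of a connected overlap
    component and inherits the union of its members' term sets and source
    ids.  Adjacent but non-overlapping intervals (e.g. 1-10 and 11-20) are
    not merged.  Output is sorted by (accession, start) and contains no two
    overlapping regions on one accession.
    """
    out: list[AnnotatedRegion] = []
    keyed = sorted(regions, key=lambda r: (r.accession, r.start, r.end))
    for _, group in groupby(keyed, key=lambda r: r.accession):
        block: list[AnnotatedRegion] = []
        cur_end = -1
        for region in group:
            if block and region.start <= cur_end:
                block.append(region)
                cur_end = max(cur_end, region.end)
            else:
                if block:
                    out.append(_merge_block(block))
                block = [region]
                cur_end = region.end
        if block:
            out.append(_merge_block(block))
    return out


def _merge_block(block: list[AnnotatedRegion]) -> AnnotatedRegion:
    if len(block) == 1:
        return block[0]
    first = block[0]
    return AnnotatedRegion(
        accession=first.accession,
        start=min(r.start for r in block),
        end=max(r.end for r in block),
        structural_state_terms=frozenset().union(
            *(r.structural_state_terms for r in block)
        ),
        transition_terms=frozenset().union(*(r.transition_terms for r in block)),
        function_terms=frozenset().union(*(r.function_terms for r in block)),
        evidence_terms=frozenset().union(*(r.evidence_terms for r in block)),
        source_ids=frozenset().union(*(r.source_ids for r in block)),
    )


def split_by_length(
    regions: list[AnnotatedRegion], min_long: int = 30
) -> tuple[list[AnnotatedRegion], list[AnnotatedRegion]]:
    """Partition regions into (long, short) by length.

    A region with at least ``min_long`` residues is long; anything shorter
    is short.  The default of 30 residues is the conventional boundary
    between short disordered segments and long disordered regions.
    """
    if min_long < 1:
        raise ValueError(f"min_long must be >= 1, got {min_long}")
    long_regions = [r for r in regions if r.length >= min_long]
    short_regions = [r for r in regions if r.length < min_long]
    return long_regions, short_regions


def apply_redundancy_filter(
    proteins: list[ProteinRecord],
    clusters: list[Cluster] | None = None,
    identity_threshold: float = 0.40,
) -> list[ProteinRecord]:
    """Reduce a protein set to sequence-redundancy-filtered representatives.

    When CD-HIT cluster output is supplied, exactly the starred
    representatives are kept (input order preserved).  Without clusters a
    greedy fallback runs: proteins are visited longest-first and a sequence
    is dropped when its ungapped pairwise identity to any already-kept
    sequence exceeds ``identity_threshold``.  Identity is the number of
    matching positions (compared left-aligned, no gaps) divided by the
    shorter length — a deliberately naive stand-in so the full pipeline
    runs on synthetic data without external tools.
    """
    if clusters is not None:
        known = {p.accession for p in proteins}
        reps: set[str] = set()
        for cluster in clusters:
            for member in cluster.members:
                if member not in known:
                    raise ValueError(f"clustered id {member!r} not among proteins")
            reps.add(cluster.representative)
        return [p for p in proteins if p.accession in reps]

    kept: list[ProteinRecord] = []
    for cand in sorted(proteins, key=lambda p: (-p.length, p.accession)):
        if all(
            _pairwise_identity(cand.sequence, k.sequence) <= identity_threshold
            for k in kept
        ):
            kept.append(cand)
    order = {p.accession: i for i, p in enumerate(proteins)}
    kept.sort(key=lambda p: order[p.accession])
    return kept


def _pairwise_identity(a: str, b: str) -> float:
    shorter = min(len(a), len(b))
    if shorter == 0:
        return 0.0
    matches = sum(1 for x, y in zip(a, b) if x == y)
    return matches / shorter


def summarize(regions: list[AnnotatedRegion]) -> RegionSetSummary:
    """Count regions, residues (sum of lengths) and distinct proteins."""
    return RegionSetSummary(
        n_regions=len(regions),
        n_residues=sum(r.length for r in regions),
        n_proteins=len({r.accession for r in regions}),
    )
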