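"""Ontology-term distributions and per-quadrant enrichment.

Regions carry ECO evidence terms, IDPO structural/transition terms and GO
function terms.  These analyses count, per namespace, how often each term
occurs in a region set (a region with several terms contributes to each of
them) and how the term's share within one agreement quadrant compares with
its share in the whole set.

Enrichment is reported as a plain ratio of fractions (and its log2); no
hypothesis test is attached — the counts are emitted so users can apply
whatever statistic suits their question.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass

from .terms import term_namespace
from .types import QUADRANTS, AnnotatedRegion

#: sentinel for log2(0) in enrichment output
NEG_INF = float("-inf")


@dataclass(frozen=True)
class TermDistribution:
    """Counts of regions per term, after a minimum-occurrence filter.

    ``total`` is the number of regions considered; ``counts`` only keeps
    terms occurring at least ``min_count`` times.  Terms rarer than the
    default threshold of 10 occurrences are dropped because their
    per-quadrant breakdowns are dominated by noise.
    """

    unit: str
    counts: dict[str, int]
    total: int
    min_count: int

    def fraction(self, term: str) -> float:
        return self.counts[term] / self.total if self.total else 0.0


@dataclass(frozen=True)
class TermEnrichment:
    """Per-quadrant enrichment of one term."""

    quadrant_fraction: float
    overall_fraction: float
    ratio: float
    log2_ratio: float
    quadrant_count: int


@dataclass(frozen=True)
class EnrichmentTable:
    """term -> quadrant -> enrichment, plus the overall distribution."""

    overall: TermDistribution
    per_quadrant: dict[str, dict[str, TermEnrichment]]
    quadrant_totals: dict[str, int]


def _terms_of(region: AnnotatedRegion, namespace: str) -> frozenset[str]:
    if namespace == "all":
        return region.all_terms
    return frozenset(t for t in region.all_terms if term_namespace(t) == namespace)


def term_distribution(
    regions: list[AnnotatedRegion],
    namespace: str = "all",
    min_count: int = 10,
) -> TermDistribution:
    """Count regions carrying each term of a namespace.

    ``namespace`` is one of ``ECO``, ``IDPO``, ``GO`` or ``all``.  A region
    with k distinct terms in the namespace contributes one count to each of
    the k terms.  Terms with fewer than ``min_count`` occurrences are
    dropped from the result.
    """
    counter: Counter[str] = Counter()
    for region in regions:
        counter.update(_terms_of(region, namespace))
    counts = {t: c for t, c in counter.items() if c >= min_count}
    return TermDistribution(
        unit="regions", counts=counts, total=len(regions), min_count=min_count
    )


def quadrant_enrichment(
    regions_with_quadrants: list[tuple[AnnotatedRegion, str]],
    namespace: str = "all",
    min_count: int = 10,
) -> EnrichmentTable:
    """Per-quadrant term enrichment relative to the overall distribution.

    The overall term fraction is computed on all regions; within each
    quadrant the same fraction is computed on that quadrant's regions, and
    their ratio (with log2) quantifies over-/under-representation.  The
    ``min_count`` filter applies to overall counts only, so a term retained
    overall is reported in every quadrant even where absent (fraction 0,
    ratio 0, log2 reported as -inf).
    """
    regions = [r for r, _ in regions_with_quadrants]
    overall = term_distribution(regions, namespace, min_count)
    quadrant_members: dict[str, list[AnnotatedRegion]] = {q: [] for q in QUADRANTS}
    for region, quadrant in regions_with_quadrants:
        if quadrant not in quadrant_members:
            raise ValueError(f"unknown quadrant {quadrant!r}")
        quadrant_members[quadrant].append(region)

    per_quadrant: dict[str, dict[str, TermEnrichment]] = {}
    for q, members in quadrant_members.items():
        q_counter: Counter[str] = Counter()
        for region in members:
            q_counter.update(_terms_of(region, namespace))
        n_q = len(members)
        table: dict[str, TermEnrichment] = {}
        for term in overall.counts:
            qc = q_counter.get(term, 0)
            qf = qc / n_q if n_q else 0.0
            of = overall.fraction(term)
            ratio = qf / of if of > 0 else 0.0
            table[term] = TermEnrichment(
                quadrant_fraction=qf,
                overall_fraction=of,
                ratio=ratio,
                log2_ratio=math.log2(ratio) if ratio > 0 else NEG_INF,
                quadrant_count=qc,
            )
        per_quadrant[q] = table
    return EnrichmentTable(
        overall=overall,
        per_quadrant=per_quadrant,
        quadrant_totals={q: len(m) for q, m in quadrant_members.items()},
    )


def subset_by_term(
    regions: list[AnnotatedRegion], term_ids: list[str] | set[str]
) -> list[AnnotatedRegion]:
    """Regions carrying at least one of the requested terms (any category)."""
    wanted = set(term_ids)
    hit = [r for r in regions if r.all_terms & wanted]
    if not hit and wanted:
        present = set().union(*(r.all_terms for r in regions)) if regions else set()
        if not (wanted & present):
            warnings.warn(
                f"no region carries any of {sorted(wanted)}", stacklevel=2
            )
    return hit
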