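"""Genomic-context classification and tolerant circRNA set matching.

Classification assigns each circRNA exactly one category with precedence
exonic > intronic > antisense > intergenic. ``exonic`` requires both
back-splice sites to fall within exons of a single same-strand gene (the
permissive rule); ``strict_boundaries=True`` additionally requires the sites
to coincide with annotated exon boundaries.

Set matching treats two loci as the same circRNA when chromosome and strand
agree and both the start and end offsets lie within a +/-5 nt window — the
convention used when comparing predictions from different detection tools.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .io_formats import CircRecord, GeneModel, GeneModelSet

logger = logging.getLogger("circage")


class GenomicCategory(str, Enum):
    EXONIC = "exonic"
    INTRONIC = "intronic"
    ANTISENSE = "antisense"
    INTERGENIC = "intergenic"


@dataclass(frozen=True)
class OverlapPair:
    query_id: str
    subject_id: str
    start_offset: int  # subject.start - query.start
    end_offset: int


@dataclass(frozen=True)
class MatchSummary:
    n_query: int
    n_subject: int
    n_query_matched: int
    n_subject_matched: int
    jaccard: float


@dataclass
class MatchResult:
    pairs: list[OverlapPair]
    summary: MatchSummary


def _strands_compatible(a: str, b: str) -> bool:
    # "." is a wildcard: detection tools disagree on strand assignment.
    return a == b or a == "." or b == "."


def _site_in_exons(pos: int, gene: GeneModel) -> bool:
    return any(s <= pos < e for s, e in gene.exons)


def _site_at_boundary(circ: CircRecord, gene: GeneModel) -> bool:
    starts = {s for s, _ in gene.exons}
    ends = {e for _, e in gene.exons}
    return circ.start in starts and circ.end in ends


def classify_genomic_context(
    circ: CircRecord, models: GeneModelSet, strict_boundaries: bool = False
) -> GenomicCategory:
    """Classify one circRNA by its overlap with annotated genes.

    A chromosome absent from the models yields ``intergenic`` with a logged
    warning rather than an error, so partially annotated genomes degrade
    gracefully.
    """
    if not models.has_chrom(circ.chrom):
        logger.warning(
            "chromosome %s absent from gene models; %s classified intergenic",
            circ.chrom,
            circ.circ_id,
        )
        return GenomicCategory.INTERGENIC

    overlapping = models.overlapping(circ.chrom, circ.start, circ.end)
    if not overlapping:
        return GenomicCategory.INTERGENIC

    same = [g for g in overlapping if _strands_compatible(circ.strand, g.strand)]
    for gene in same:
        if strict_boundaries:
            if _site_at_boundary(circ, gene):
                return GenomicCategory.EXONIC
        elif _site_in_exons(circ.start, gene) and _site_in_exons(circ.end - 1, gene):
            return GenomicCategory.EXONIC
    if same:
        return GenomicCategory.INTRONIC
    return GenomicCategory.ANTISENSE


def classify_many(
    circs: Sequence[CircRecord], models: GeneModelSet, strict_boundaries: bool = False
) -> dict[str, GenomicCategory]:
    """Category per circ_id, plus a logged tally of the distribution."""
    out = {
        c.circ_id: classify_genomic_context(c, models, strict_boundaries)
        for c in circs
    }
    tally: dict[GenomicCategory, int] = defaultdict(int)
    for cat in out.values():
        tally[cat] += 1
    logger.info(
        "genomic distribution: %s",
        {k.value: v for k, v in sorted(tally.items(), key=lambda kv: -kv[1])},
    )
    return out


def match_circ_sets(
    query: Sequence[CircRecord],
    subject: Sequence[CircRecord],
    tolerance_nt: int = 5,
) -> MatchResult:
    """Match two circRNA sets with coordinate tolerance.

    A (query, subject) pair is reported iff chromosome and strand agree
    (``.`` matches either strand) and both |start offset| and |end offset|
    are <= ``tolerance_nt``. Each query may match several subjects. With
    tolerance 0 this reduces to exact-identity matching.

    The summary's Jaccard index treats each matched query as collapsing onto
    one subject: ``intersection / (|query| + |subject| - intersection)`` with
    intersection = number of matched queries.
    """
    if tolerance_nt < 0:
        raise ValueError(f"tolerance_nt must be >= 0, got {tolerance_nt}")

    by_chrom: dict[str, list[CircRecord]] = defaultdict(list)
    for s in subject:
        by_chrom[s.chrom].append(s)
    for recs in by_chrom.values():
        recs.sort(key=lambda r: r.start)

    pairs: list[OverlapPair] = []
    matched_q: set[str] = set()
    matched_s: set[str] = set()
    for q in query:
        for s in by_chrom.get(q.chrom, ()):
            if s.start > q.start + tolerance_nt:
                break
            if s.start < q.start - tolerance_nt:
                continue
            if abs(s.end - q.end) > tolerance_nt:
                continue
            if not _strands_compatible(q.strand, s.strand):
                continue
            pairs.append(
                OverlapPair(
                    query_id=q.circ_id,
                    subject_id=s.circ_id,
                    start_offset=s.start - q.start,
                    end_offset=s.end - q.end,
                )
            )
            matched_q.add(q.circ_id)
            matched_s.add(s.circ_id)

    n_q = len({r.circ_id for r in query})
    n_s = len({r.circ_id for r in subject})
    inter = len(matched_q)
    union = n_q + n_s - inter
    summary = MatchSummary(
        n_query=n_q,
        n_subject=n_s,
        n_query_matched=inter,
        n_subject_matched=len(matched_s),
        jaccard=inter / union if union else 0.0,
    )
    logger.info(
        "matched %d/%d query and %d/%d subject circRNAs (tolerance %d nt)",
        inter, n_q, len(matched_s), n_s, tolerance_nt,
    )
    return MatchResult(pairs=pairs, summary=summary)
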