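"""Domain accretion statistic: longest internal exon in inter-domain versus
post-terminal-domain segments.

For every gene encoding at least one SCOP domain, two kinds of protein
segments are extracted: group A, between two consecutive SCOP domains, and
group B, downstream of the last SCOP domain.  In each segment the longest
candidate internal exon is identified; comparing mean longest-exon length in
group A against group B as a function of segment length tests whether long
exons precede the acquisition of a downstream domain.

Candidate rules (evaluated per transcript on its own residue coordinates):
group A — internal exons that encode the C-terminal residue of the upstream
domain, plus internal exons whose first encoded residue lies strictly
between the two domains; group B — internal exons whose last encoded residue
lies downstream of the last domain's C-terminal residue.  Genes without SCOP
domains are ignored.  Unlike every other analysis, the longest-exon search
runs on the variant-redundant exon set: candidates are gathered per
transcript and unioned per gene.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .annotations import IntervalAnnotation, merge_intervals
from .gene_models import Exon, ExonResidueMap, GeneModel, map_exons_to_residues
from .stats import sem

logger = logging.getLogger("exarch")

__all__ = [
    "DomainSegment",
    "extract_segments",
    "candidate_exons",
    "gene_segments",
    "longest_exon_by_distance_bin",
]

NT_PER_RESIDUE = 3


@dataclass
class DomainSegment:
    """A group A (inter-domain) or group B (post-terminal-domain) segment."""

    group: str  # "A" or "B"
    gene_id: str
    span_start: int  # first residue after the upstream domain
    span_end: int  # group A: last residue before the next domain; B: protein end
    upstream_domain_end: int
    downstream_domain_start: int | None  # None for group B
    candidates: list[tuple[Exon, int]] = field(default_factory=list)  # (exon, first_residue)

    @property
    def distance_residues(self) -> int:
        return max(0, self.span_end - self.span_start + 1)

    @property
    def distance_nt(self) -> int:
        return self.distance_residues * NT_PER_RESIDUE

    @property
    def longest_exon_nt(self) -> int | None:
        """Length of the longest candidate; ties broken by the 5'-most exon
        (smallest first encoded residue)."""
        if not self.candidates:
            return None
        best = min(self.candidates, key=lambda c: (-c[0].nt_length, c[1]))
        return best[0].nt_length


def extract_segments(
    gene_id: str,
    domains: IntervalAnnotation,
    protein_length: int,
) -> list[DomainSegment]:
    """Group A segments between consecutive domains and the single group B
    segment downstream of the last domain."""
    merged = merge_intervals(domains.intervals, merge_adjacent=False)
    if not merged:
        raise ValueError(f"gene {gene_id}: no domains; genes without domains are ignored")
    segments: list[DomainSegment] = []
    for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
        segments.append(
            DomainSegment(
                group="A",
                gene_id=gene_id,
                span_start=e1 + 1,
                span_end=s2 - 1,
                upstream_domain_end=e1,
                downstream_domain_start=s2,
            )
        )
    last_end = merged[-1][1]
    segments.append(
        DomainSegment(
            group="B",
            gene_id=gene_id,
            span_start=last_end + 1,
            span_end=protein_length,
            upstream_domain_end=last_end,
            downstream_domain_start=None,
        )
    )
    return segments


def candidate_exons(
    segment: DomainSegment, exon_maps: Sequence[ExonResidueMap]
) -> list[tuple[Exon, int]]:
    """Internal exons qualifying as longest-exon candidates for a segment."""
    out = []
    for m in exon_maps:
        if m.exon_ref.position_class != "internal":
            continue
        if segment.group == "A":
            encodes_cterm = m.first_residue <= segment.upstream_domain_end <= m.last_residue
            starts_between = (
                segment.upstream_domain_end < m.first_residue < segment.downstream_domain_start
            )
            if encodes_cterm or starts_between:
                out.append((m.exon_ref, m.first_residue))
        else:
            if m.last_residue > segment.upstream_domain_end:
                out.append((m.exon_ref, m.first_residue))
    return out


def gene_segments(
    gene: GeneModel,
    domains_by_protein: Mapping[str, IntervalAnnotation],
    cds_includes_stop: bool = True,
) -> list[DomainSegment]:
    """Per-gene segments with candidates unioned over transcript variants.

    The representative transcript (most domains, then longest protein)
    defines the gene's segments; every transcript whose protein carries an
    identical domain annotation contributes candidates to the segment with
    the same ordinal, so shared exons are evaluated in each variant's own
    coordinates and unioned by genomic position.
    """
    annotated = [
        t for t in gene.transcripts
        if domains_by_protein.get(t.protein_id) is not None
        and domains_by_protein[t.protein_id].intervals
    ]
    if not annotated:
        return []

    def rank(t):
        return (len(domains_by_protein[t.protein_id].intervals),
                t.protein_length(cds_includes_stop))

    rep = max(annotated, key=rank)
    rep_dom = domains_by_protein[rep.protein_id]
    segments = extract_segments(
        gene.gene_id, rep_dom, rep.protein_length(cds_includes_stop)
    )

    for t in annotated:
        dom = domains_by_protein[t.protein_id]
        if dom.intervals != rep_dom.intervals:
            if t is not rep:
                logger.info(
                    "gene %s: transcript %s has a different domain layout; "
                    "only the representative contributes",
                    gene.gene_id, t.transcript_id,
                )
            if t is not rep:
                continue
        t_segments = (
            segments
            if t is rep
            else extract_segments(gene.gene_id, dom, t.protein_length(cds_includes_stop))
        )
        maps = map_exons_to_residues(t, cds_includes_stop)
        for target, source in zip(segments, t_segments):
            if target.group != source.group:
                continue
            for exon, first in candidate_exons(source, maps):
                if all(exon.key != c[0].key for c in target.candidates):
                    target.candidates.append((exon, first))
    return segments


def longest_exon_by_distance_bin(
    segments: Iterable[DomainSegment],
    bin_width_nt: int = 600,
    min_n: int = 25,
) -> list[dict]:
    """Mean and SEM of the longest candidate exon per distance bin and group.

    Segments with empty candidate sets are excluded.  A bin is reported only
    when BOTH groups reach ``min_n`` segments in it (minimum number
    requirement); with no qualifying bin the output is empty with a warning.
    """
    per_bin: dict[int, dict[str, list[int]]] = {}
    for seg in segments:
        longest = seg.longest_exon_nt
        if longest is None:
            continue
        b = seg.distance_nt // bin_width_nt
        per_bin.setdefault(b, {"A": [], "B": []})[seg.group].append(longest)

    out = []
    for b in sorted(per_bin):
        groups = per_bin[b]
        if len(groups["A"]) < min_n or len(groups["B"]) < min_n:
            continue
        for g in ("A", "B"):
            vals = groups[g]
            out.append(
                {
                    "group": g,
                    "distance_bin": f"{b * bin_width_nt}-{(b + 1) * bin_width_nt - 1}",
                    "bin_index": b,
                    "n": len(vals),
                    "mean_longest_nt": float(sum(vals) / len(vals)),
                    "sem": sem(vals),
                }
            )
    if not out:
        logger.warning(
            "no distance bin satisfies the minimum number requirement (n >= %d "
            "in both groups); no means reported", min_n,
        )
    return out
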