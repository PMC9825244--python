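"""Constrained-exon statistics against SCOP structural domains.

An internal exon is *constrained* when the residue interval it encodes is
entirely contained within a single SCOP domain; all other internal exons are
unconstrained.  The analytic null model gives the probability that a random
placement of an exon encoding y residues has both boundaries strictly inside
a domain of length x_i:

    P(y) = sum_i (x_i - y - 1) / (L - y + 1)   for x_i > y + 1, else 0 terms,

where L is the total number of residues encoded by internal exons and the
sum runs over all SCOP domains encoded by internal exons.  Observed and
expected fractions are compared per exon-length bin; their ratio below one
indicates depletion of constrained exons.

The observed classification uses interval containment while the null model
counts strictly interior placements; the two differ at domain boundaries and
both are kept exactly as defined.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotations import IntervalAnnotation, merge_intervals
from .gene_models import ExonResidueMap, InternalExonRecord
from .idr_analysis import LengthBinning

logger = logging.getLogger("exarch")

__all__ = [
    "ConstrainedExpectationContext",
    "is_constrained",
    "expected_constrained_probability",
    "constrained_fractions_by_bin",
    "subsample_domains",
    "build_expectation_context",
]


@dataclass(frozen=True)
class ConstrainedExpectationContext:
    """Null-model context: L (total residues encoded by internal exons,
    rounded to the nearest integer) and the lengths x_i of SCOP domains
    encoded by internal exons."""

    L: int
    domain_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("L must be positive")
        if self.domain_lengths and self.L < max(self.domain_lengths):
            raise ValueError("L smaller than the longest domain")


def is_constrained(
    exon_map: ExonResidueMap | tuple[int, int], domains: IntervalAnnotation | None
) -> bool:
    """True iff the exon's residue interval lies within one single domain."""
    if isinstance(exon_map, ExonResidueMap):
        if exon_map.exon_ref.position_class != "internal":
            raise ValueError("only internal exons are classified")
        first, last = exon_map.first_residue, exon_map.last_residue
    else:
        first, last = exon_map
    if last < first or first < 1:
        raise ValueError("exon must encode at least one residue")
    if domains is None:
        return False
    return any(s <= first and last <= e for s, e in domains.intervals)


def expected_constrained_probability(
    y: int, ctx: ConstrainedExpectationContext, exact: bool = False
) -> float | Fraction:
    """Null probability that an exon encoding y residues is constrained.

    Equals the fraction of the L - y + 1 possible placements of a y-residue
    window whose endpoints are both strictly interior to one domain, summed
    over domains.  With ``exact`` the value is returned as a Fraction.
    """
    if y < 1:
        raise ValueError("y must be >= 1")
    if y >= ctx.L:
        raise ValueError(f"y={y} must be smaller than L={ctx.L}")
    denom = ctx.L - y + 1
    if exact:
        total = sum(
            (Fraction(x - y - 1, denom) for x in ctx.domain_lengths if x > y + 1),
            Fraction(0),
        )
        if total > 1:
            logger.warning("expected constrained probability %s > 1; clipped", total)
            total = Fraction(1)
        return total
    numer = sum(x - y - 1 for x in ctx.domain_lengths if x > y + 1)
    total_f = numer / denom
    if total_f > 1.0:
        logger.warning("expected constrained probability %s > 1; clipped", total_f)
        total_f = 1.0
    return total_f


def build_expectation_context(
    records: Iterable[InternalExonRecord],
    domains_by_protein: Mapping[str, IntervalAnnotation],
) -> ConstrainedExpectationContext:
    """Pool L and domain lengths over a genome's internal exons.

    L sums the residues encoded by all (coding) internal exons.  A domain
    counts as encoded by internal exons if its interval overlaps at least one
    internal exon's residue interval; overlapping domain annotations on the
    same protein are merged first, as overlapping SCOP hits are artifacts.
    """
    L = 0
    spans_by_protein: dict[str, list[tuple[int, int]]] = {}
    for rec in records:
        if rec.first_residue is None:
            continue
        L += rec.y
        spans_by_protein.setdefault(rec.protein_id, []).append(
            (rec.first_residue, rec.last_residue)
        )
    domain_lengths: list[int] = []
    for pid, spans in spans_by_protein.items():
        ann = domains_by_protein.get(pid)
        if ann is None:
            continue
        merged = merge_intervals(ann.intervals, merge_adjacent=False)
        if len(merged) < len(ann.intervals):
            logger.warning("%s: overlapping domain annotations merged", pid)
        for ds, de in merged:
            if any(s <= de and ds <= e for s, e in spans):
                domain_lengths.append(de - ds + 1)
    return ConstrainedExpectationContext(L=L, domain_lengths=tuple(domain_lengths))


@dataclass(frozen=True)
class ConstrainedBin:
    bin_label: str
    n: int
    observed_fraction: float
    expected_fraction: float

    @property
    def ratio(self) -> float:
        if not math.isfinite(self.expected_fraction) or self.expected_fraction == 0:
            return float("nan")
        return self.observed_fraction / self.expected_fraction


def constrained_fractions_by_bin(
    records: Sequence[InternalExonRecord],
    domains_by_protein: Mapping[str, IntervalAnnotation],
    binning: LengthBinning | None = None,
    ctx: ConstrainedExpectationContext | None = None,
    use_coding_length: bool = False,
) -> list[ConstrainedBin]:
    """Observed and expected constrained fractions per exon-length bin.

    Observed is the fraction of coding internal exons in the bin contained in
    a single domain; expected is the mean over those exons of the null
    probability at their y.  Bins with no coding exons are reported with NaN
    fractions.
    """
    binning = binning or LengthBinning()
    if ctx is None:
        ctx = build_expectation_context(records, domains_by_protein)
    # suffix sums over sorted domain lengths make the per-exon expected
    # probability O(log n_domains)
    xs = np.sort(np.asarray(ctx.domain_lengths, dtype=np.int64))
    suffix = np.concatenate([np.cumsum(xs[::-1])[::-1], [0]])
    n = [0] * binning.n_bins
    constrained = [0] * binning.n_bins
    expected_sum = [0.0] * binning.n_bins
    for rec in records:
        if rec.first_residue is None:
            continue
        length = rec.exon.coding_nt_length if use_coding_length else rec.nt_length
        i = binning.assign(length)
        if i is None:
            continue
        n[i] += 1
        if is_constrained(
            (rec.first_residue, rec.last_residue), domains_by_protein.get(rec.protein_id)
        ):
            constrained[i] += 1
        y = rec.y
        if y < ctx.L:
            j = int(np.searchsorted(xs, y + 1, side="right"))
            numer = suffix[j] - (len(xs) - j) * (y + 1)
            expected_sum[i] += min(1.0, float(numer) / (ctx.L - y + 1))
    out = []
    for i in range(binning.n_bins):
        out.append(
            ConstrainedBin(
                bin_label=binning.label(i),
                n=n[i],
                observed_fraction=constrained[i] / n[i] if n[i] else float("nan"),
                expected_fraction=expected_sum[i] / n[i] if n[i] else float("nan"),
            )
        )
    return out


def subsample_domains(
    domains_by_protein: Mapping[str, IntervalAnnotation],
    fraction: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> dict[str, IntervalAnnotation]:
    """Keep a random floor(fraction * N) of the pooled domains.

    Emulates the robustness check against unidentified ("latent") domains:
    half of the domain assignments are discarded at random and the analyses
    repeated.  Deterministic under a fixed seed.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    pool = [
        (pid, iv)
        for pid, ann in sorted(domains_by_protein.items())
        for iv in ann.intervals
    ]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keep_n = int(math.floor(fraction * len(pool)))
    idx = sorted(rng.choice(len(pool), size=keep_n, replace=False)) if pool else []
    kept: dict[str, list[tuple[int, int]]] = {}
    for i in idx:
        pid, iv = pool[int(i)]
        kept.setdefault(pid, []).append(iv)
    out = {}
    for pid, ivs in kept.items():
        src = domains_by_protein[pid].source
        out[pid] = IntervalAnnotation(pid, src, "DOMAIN", tuple(sorted(ivs)))
    return out
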