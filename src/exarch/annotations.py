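"""Per-protein interval annotations: intrinsically disordered regions (IDRs)
and SCOP structural domains, both stored as 1-based inclusive residue
intervals labeled by their source (predictor or classification scheme).

Multiple IDR predictors are kept as parallel annotation sets and every
analysis is run per source — never merged — so per-predictor robustness can
be assessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

logger = logging.getLogger("exarch")

KINDS = ("IDR", "DOMAIN")


def merge_intervals(
    intervals: Iterable[tuple[int, int]], merge_adjacent: bool = True
) -> list[tuple[int, int]]:
    """Sort and merge overlapping (and, by default, touching) intervals."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    gap = 1 if merge_adjacent else 0
    for s, e in ivs:
        if merged and s <= merged[-1][1] + gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


@dataclass(frozen=True)
class IntervalAnnotation:
    """Intervals of one kind from one source on one protein."""

    protein_id: str
    source: str
    kind: str
    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown annotation kind {self.kind!r}")
        prev_end = 0
        for s, e in self.intervals:
            if s > e:
                raise ValueError(f"interval start {s} > end {e}")
            if s <= prev_end:
                raise ValueError("intervals not sorted/disjoint after normalization")
            prev_end = e

    @property
    def lengths(self) -> list[int]:
        """Interval lengths in residues (domain lengths x_i for DOMAIN kind)."""
        return [e - s + 1 for s, e in self.intervals]

    def total_length(self) -> int:
        return sum(self.lengths)


@dataclass
class ProteinAnnotationSet:
    protein_id: str
    protein_length: int
    idr_sets: dict[str, IntervalAnnotation] = field(default_factory=dict)
    domain_set: IntervalAnnotation | None = None

    def __post_init__(self) -> None:
        for ann in list(self.idr_sets.values()) + (
            [self.domain_set] if self.domain_set else []
        ):
            for s, e in ann.intervals:
                if e > self.protein_length:
                    raise ValueError(
                        f"{self.protein_id}: interval {s}-{e} exceeds protein "
                        f"length {self.protein_length}"
                    )


def read_interval_table(
    tsv_path: str,
    kind: str,
    protein_lengths: Mapping[str, int] | None = None,
) -> list[IntervalAnnotation]:
    """Read a TSV of residue intervals (protein_id, source, start, end).

    Per (protein, source) the intervals are normalized: sorted, with
    overlapping or touching intervals merged (warned, since predictors
    should not emit them).  Rows with start > end, or exceeding the protein
    length when lengths are supplied, are rejected with a logged line number.
    A header line is detected and skipped.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown annotation kind {kind!r}")
    raw: dict[tuple[str, str], list[tuple[int, int]]] = {}
    with open(tsv_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{tsv_path}:{lineno}: expected >=4 tab-separated columns")
            pid, source, start_s, end_s = fields[0], fields[1], fields[2], fields[3]
            if lineno == 1 and not (start_s.lstrip("-").isdigit()):
                continue  # header
            start, end = int(start_s), int(end_s)
            if start > end or start < 1:
                logger.warning("%s:%d: bad interval %d-%d rejected", tsv_path, lineno, start, end)
                continue
            if protein_lengths is not None and pid in protein_lengths:
                if end > protein_lengths[pid]:
                    logger.warning(
                        "%s:%d: interval %d-%d exceeds protein length %d; rejected",
                        tsv_path, lineno, start, end, protein_lengths[pid],
                    )
                    continue
            raw.setdefault((pid, source), []).append((start, end))

    annotations = []
    for (pid, source), ivs in sorted(raw.items()):
        merged = merge_intervals(ivs)
        if len(merged) < len(ivs):
            logger.warning(
                "%s/%s: %d overlapping or touching interval(s) merged",
                pid, source, len(ivs) - len(merged),
            )
        annotations.append(IntervalAnnotation(pid, source, kind, tuple(merged)))
    return annotations


def annotations_by_protein(
    annotations: Iterable[IntervalAnnotation],
) -> dict[str, dict[str, IntervalAnnotation]]:
    """Index annotations as protein_id -> source -> annotation."""
    out: dict[str, dict[str, IntervalAnnotation]] = {}
    for ann in annotations:
        out.setdefault(ann.protein_id, {})[ann.source] = ann
    return out


def overlap_length(interval: tuple[int, int], annotation: IntervalAnnotation) -> int:
    s, e = interval
    return sum(max(0, min(e, ie) - max(s, is_) + 1) for is_, ie in annotation.intervals)


def idr_fraction(residues: tuple[int, int], annotation: IntervalAnnotation | None) -> float:
    """Fraction of a residue interval covered by the annotation's intervals."""
    s, e = residues
    if e < s:
        raise ValueError(f"empty residue interval {s}-{e}")
    if annotation is None:
        return 0.0
    return overlap_length(residues, annotation) / (e - s + 1)


def write_interval_table(annotations: Iterable[IntervalAnnotation], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tsource\tstart\tend\n")
        for ann in annotations:
            for s, e in ann.intervals:
                fh.write(f"{ann.protein_id}\t{ann.source}\t{s}\t{e}\n")


def convert_disopred(
    diso_path: str, protein_id: str, source: str = "DISOPRED3"
) -> IntervalAnnotation:
    """Convert DISOPRED-style per-residue output into an interval annotation.

    Expected data lines: ``<index> <residue> <mark> <score>`` where the mark
    is ``*`` for a disorder call and ``.`` otherwise; comment lines start
    with '#'.
    """
    calls: list[int] = []
    with open(diso_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3 or not fields[0].isdigit():
                continue
            if fields[2] == "*":
                calls.append(int(fields[0]))
    intervals: list[tuple[int, int]] = []
    for idx in calls:
        if intervals and idx == intervals[-1][1] + 1:
            intervals[-1] = (intervals[-1][0], idx)
        else:
            intervals.append((idx, idx))
    return IntervalAnnotation(protein_id, source, "IDR", tuple(intervals))
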