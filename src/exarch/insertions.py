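"""Lineage-specific insertion detection from three-way ortholog alignments.

Given protein alignments of an outgroup (human-role) and two ingroup lineages
(mouse-role and rat-role), a maximal run of columns in which the target
lineage has residues while BOTH other sequences are gapped is taken as a
segment inserted on the target lineage after the two ingroups diverged — a
segment present in only one ingroup is unlikely to have been deleted
independently in the other ingroup and the outgroup.  Detected segments are
mapped onto the exons of the target gene model; segments that coincide
exactly with one or more entire exons are removed (those reflect whole-exon
gain, not elongation within an exon), and the remainder are compared with the
genomic background for disorder content and host-exon domain constraint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .annotations import IntervalAnnotation, overlap_length
from .constrained import is_constrained
from .gene_models import ExonResidueMap
from .idr_analysis import LengthBinning

logger = logging.getLogger("exarch")

__all__ = [
    "TrioAlignment",
    "InsertionSegment",
    "read_trio_alignments",
    "detect_lineage_insertions",
    "assign_host_exons",
    "filter_whole_exon_insertions",
    "insertion_idr_contrast",
    "host_exon_constraint_by_bin",
]

GAP = "-"


@dataclass(frozen=True)
class TrioAlignment:
    """One aligned ortholog trio; sequences include gap characters."""

    outgroup_id: str
    lineage1_id: str
    lineage2_id: str
    outgroup: str
    lineage1: str
    lineage2: str

    def __post_init__(self) -> None:
        if not (len(self.outgroup) == len(self.lineage1) == len(self.lineage2)):
            raise ValueError("aligned sequences must have equal lengths")

    def ungapped(self, role: str) -> str:
        return getattr(self, role).replace(GAP, "")


@dataclass(frozen=True)
class InsertionSegment:
    """A lineage-specific inserted residue interval on the target protein."""

    target_lineage: str  # "lineage1" or "lineage2"
    protein_id: str
    start: int  # 1-based residue coordinates on the target protein
    end: int
    host_exons: tuple[ExonResidueMap, ...] = ()
    whole_exon: bool = False

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("empty insertion interval")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_trio_alignments(manifest_path: str, base_dir: str = ".") -> list[TrioAlignment]:
    """Load trio alignments listed in a manifest TSV.

    Manifest columns: alignment_file, outgroup_id, lineage1_id, lineage2_id.
    Each alignment file is aligned FASTA with exactly those three records.
    """
    import os

    trios = []
    with open(manifest_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "alignment_file":
                continue
            if len(fields) < 4:
                raise ValueError(f"{manifest_path}:{lineno}: expected 4 columns")
            path, og, l1, l2 = fields[:4]
            records = {
                r.id: str(r.seq) for r in SeqIO.parse(os.path.join(base_dir, path), "fasta")
            }
            missing = {og, l1, l2} - set(records)
            if missing:
                raise ValueError(f"{path}: missing sequence(s) {sorted(missing)}")
            trios.append(
                TrioAlignment(og, l1, l2, records[og], records[l1], records[l2])
            )
    return trios


def detect_lineage_insertions(aln: TrioAlignment, target: str) -> list[InsertionSegment]:
    """Maximal runs where the target has residues and both others have gaps.

    Runs are converted from alignment columns to 1-based residue coordinates
    on the target protein.  Runs separated by even a single shared column are
    reported as distinct segments.
    """
    if target not in ("lineage1", "lineage2"):
        raise ValueError("target must be 'lineage1' or 'lineage2'")
    other = aln.lineage2 if target == "lineage1" else aln.lineage1
    tgt = getattr(aln, target)
    pid = getattr(aln, f"{target}_id")

    segments: list[InsertionSegment] = []
    residue = 0
    run_start: int | None = None
    for col in range(len(tgt)):
        t_res = tgt[col] != GAP
        if t_res:
            residue += 1
        specific = t_res and aln.outgroup[col] == GAP and other[col] == GAP
        if specific and run_start is None:
            run_start = residue
        elif not specific and run_start is not None:
            segments.append(
                InsertionSegment(target, pid, run_start, residue - (1 if t_res else 0))
            )
            run_start = None
    if run_start is not None:
        segments.append(InsertionSegment(target, pid, run_start, residue))
    return segments


def assign_host_exons(
    segment: InsertionSegment,
    exon_maps: Sequence[ExonResidueMap],
    whole_exon_tolerance: int = 0,
) -> InsertionSegment:
    """Attach the exons whose residue spans overlap the inserted interval.

    The whole-exon flag is set when the interval coincides (within the
    tolerance, default exact) with the union of the full residue spans of one
    or more consecutive exons.
    """
    maps = sorted(exon_maps, key=lambda m: m.first_residue)
    hosts = tuple(
        m for m in maps if m.first_residue <= segment.end and segment.start <= m.last_residue
    )
    whole = False
    for i in range(len(maps)):
        if abs(maps[i].first_residue - segment.start) > whole_exon_tolerance:
            continue
        for j in range(i, len(maps)):
            if j > i and maps[j].first_residue != maps[j - 1].last_residue + 1:
                break  # not consecutive in residue space
            if abs(maps[j].last_residue - segment.end) <= whole_exon_tolerance:
                whole = True
                break
        if whole:
            break
    return replace(segment, host_exons=hosts, whole_exon=whole)


def filter_whole_exon_insertions(
    segments: Iterable[InsertionSegment],
) -> tuple[list[InsertionSegment], list[InsertionSegment]]:
    """Split segments into (retained within-exon insertions, removed).

    Removed segments are those coinciding with entire exons, plus segments
    overlapping no internal exon (insertions in terminal exons are outside
    the internal-exon statistics and are logged).
    """
    retained, removed = [], []
    for seg in segments:
        internal_hosts = [
            m for m in seg.host_exons if m.exon_ref.position_class == "internal"
        ]
        if seg.whole_exon:
            removed.append(seg)
        elif not internal_hosts:
            logger.info(
                "insertion %s:%d-%d overlaps no internal exon; excluded",
                seg.protein_id, seg.start, seg.end,
            )
            removed.append(seg)
        else:
            retained.append(seg)
    return retained, removed


def _subtract_intervals(
    span: tuple[int, int], cuts: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Residue intervals of span not covered by cuts (cuts sorted, disjoint)."""
    out = []
    pos = span[0]
    for s, e in cuts:
        if e < span[0] or s > span[1]:
            continue
        if max(s, span[0]) > pos:
            out.append((pos, max(s, span[0]) - 1))
        pos = max(pos, min(e, span[1]) + 1)
    if pos <= span[1]:
        out.append((pos, span[1]))
    return out


def insertion_idr_contrast(
    segments: Sequence[InsertionSegment],
    idr_by_protein: Mapping[str, IntervalAnnotation],
    background: Iterable,  # InternalExonRecord
) -> tuple[float, float]:
    """Residue-weighted IDR fraction of inserted residues vs the rest of the
    internal-exon-encoded residues, for one annotation source."""
    if not segments:
        raise ValueError("no retained insertion segments")
    ins_by_protein: dict[str, list[tuple[int, int]]] = {}
    ins_res = ins_idr = 0
    for seg in segments:
        ann = idr_by_protein.get(seg.protein_id)
        ins_res += seg.length
        if ann is not None:
            ins_idr += overlap_length((seg.start, seg.end), ann)
        ins_by_protein.setdefault(seg.protein_id, []).append((seg.start, seg.end))

    bg_res = bg_idr = 0
    for rec in background:
        if rec.first_residue is None:
            continue
        span = (rec.first_residue, rec.last_residue)
        cuts = sorted(ins_by_protein.get(rec.protein_id, []))
        pieces = _subtract_intervals(span, cuts)
        ann = idr_by_protein.get(rec.protein_id)
        for s, e in pieces:
            bg_res += e - s + 1
            if ann is not None:
                bg_idr += overlap_length((s, e), ann)
    if bg_res == 0:
        raise ValueError("empty background")
    return ins_idr / ins_res, bg_idr / bg_res


def host_exon_constraint_by_bin(
    segments: Sequence[InsertionSegment],
    all_records: Sequence,  # InternalExonRecord
    domains_by_protein: Mapping[str, IntervalAnnotation],
    binning: LengthBinning | None = None,
) -> list[dict]:
    """Observed constrained fraction among insertion-host internal exons per
    length bin, against the constrained fraction of all internal exons
    (the expectation) in the same bin.

    An insertion spanning an exon junction contributes each overlapped
    internal exon once; an exon hosting several insertions still counts once.
    """
    binning = binning or LengthBinning()
    protein_of = {}
    hosts: dict[tuple[str, int, int], ExonResidueMap] = {}
    for seg in segments:
        for m in seg.host_exons:
            if m.exon_ref.position_class != "internal":
                continue
            key = (seg.protein_id, m.exon_ref.genomic_start, m.exon_ref.genomic_end)
            hosts[key] = m
            protein_of[key] = seg.protein_id

    n = [0] * binning.n_bins
    constrained_n = [0] * binning.n_bins
    for key, m in hosts.items():
        i = binning.assign(m.exon_ref.nt_length)
        if i is None:
            continue
        n[i] += 1
        if is_constrained(
            (m.first_residue, m.last_residue), domains_by_protein.get(protein_of[key])
        ):
            constrained_n[i] += 1

    exp_n = [0] * binning.n_bins
    exp_con = [0] * binning.n_bins
    for rec in all_records:
        if rec.first_residue is None:
            continue
        i = binning.assign(rec.nt_length)
        if i is None:
            continue
        exp_n[i] += 1
        if is_constrained(
            (rec.first_residue, rec.last_residue), domains_by_protein.get(rec.protein_id)
        ):
            exp_con[i] += 1

    out = []
    for i in range(binning.n_bins):
        obs = constrained_n[i] / n[i] if n[i] else float("nan")
        exp = exp_con[i] / exp_n[i] if exp_n[i] else float("nan")
        out.append(
            {
                "bin_label": binning.label(i),
                "n_host": n[i],
                "observed_fraction": obs,
                "expected_fraction": exp,
                "ratio": obs / exp if n[i] and exp_n[i] and exp > 0 else float("nan"),
            }
        )
    return out
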