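"""Gene models: GFF3 parsing, exon classification, and exon-to-residue mapping.

Internal exons (neither first nor last in a transcript) are the unit of every
downstream analysis.  Because one gene typically has several transcript
variants sharing exons, internal exons are deduplicated by genomic coordinates
before counting; an exon that is internal in at least one variant counts as
internal.

A coding exon is mapped to the protein residue interval it encodes.  Codons
split across an exon junction are attributed to the exon that carries the
majority (>=2) of the codon's three nucleotides, so every residue belongs to
exactly one exon and the per-exon intervals partition the protein.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import gffutils

logger = logging.getLogger("exarch")

COMPLEMENT = str.maketrans("ACGTRYKMBVDHacgtrykmbvdh", "TGCAYRMKVBHDtgcayrmkvbhd")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

POSITION_CLASSES = ("first_terminal", "internal", "last_terminal", "single")


@dataclass(frozen=True)
class Exon:
    """One exon; coordinates are 1-based inclusive genomic nt."""

    genomic_start: int
    genomic_end: int
    position_class: str
    coding_nt_length: int = 0

    def __post_init__(self) -> None:
        if self.genomic_start > self.genomic_end:
            raise ValueError(
                f"exon start {self.genomic_start} > end {self.genomic_end}"
            )
        if self.position_class not in POSITION_CLASSES:
            raise ValueError(f"unknown position class {self.position_class!r}")

    @property
    def nt_length(self) -> int:
        return self.genomic_end - self.genomic_start + 1

    @property
    def key(self) -> tuple[int, int]:
        return (self.genomic_start, self.genomic_end)


@dataclass(frozen=True)
class ExonResidueMap:
    """Residue interval encoded by one coding exon (1-based inclusive)."""

    exon_ref: Exon
    first_residue: int
    last_residue: int

    def __post_init__(self) -> None:
        if not 1 <= self.first_residue <= self.last_residue:
            raise ValueError(
                f"bad residue interval {self.first_residue}-{self.last_residue}"
            )

    @property
    def y(self) -> int:
        """Number of amino acids encoded by the exon."""
        return self.last_residue - self.first_residue + 1


@dataclass
class Transcript:
    transcript_id: str
    protein_id: str
    strand: str
    exons: list[Exon]  # transcription order
    cds_intervals: list[tuple[int, int, int]]  # (start, end, phase), transcription order
    seqid: str = ""

    @property
    def coding_nt_length(self) -> int:
        first_phase = self.cds_intervals[0][2] if self.cds_intervals else 0
        return sum(e - s + 1 for s, e, _ in self.cds_intervals) - first_phase

    def protein_length(self, cds_includes_stop: bool = True) -> int:
        n_codons = self.coding_nt_length // 3
        return n_codons - 1 if cds_includes_stop else n_codons


@dataclass
class GeneModel:
    gene_id: str
    strand: str
    transcripts: list[Transcript]
    seqid: str = ""

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id}: no transcripts")
        for t in self.transcripts:
            if t.strand != self.strand:
                raise ValueError(f"gene {self.gene_id}: strand mismatch in {t.transcript_id}")


# ---------------------------------------------------------------------------
# GFF3 parsing
# ---------------------------------------------------------------------------


def _classify_positions(n_exons: int) -> list[str]:
    if n_exons == 1:
        return ["single"]
    return ["first_terminal"] + ["internal"] * (n_exons - 2) + ["last_terminal"]


def _transcription_sort(features: list, strand: str) -> list:
    return sorted(features, key=lambda f: f.start, reverse=(strand == "-"))


def read_gene_models(
    gff3_path: str,
    cds_includes_stop: bool = True,
) -> list[GeneModel]:
    """Parse a GFF3 file with gene/mRNA/exon/CDS features into gene models.

    Exons and CDS features are normalized to transcription order on both
    strands.  Transcripts whose CDS length (after discarding the phase
    overhang of the first CDS feature) is not divisible by 3 are skipped with
    a warning rather than aborting the parse, since real gene builds contain
    such exceptions.
    """
    try:
        db = gffutils.create_db(
            str(gff3_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # pragma: no cover - gffutils error paths vary
        raise ValueError(f"malformed GFF3 {gff3_path}: {exc}") from exc

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        transcripts: list[Transcript] = []
        for mrna in db.children(gene, featuretype=("mRNA", "transcript"), level=1):
            exon_feats = _transcription_sort(
                list(db.children(mrna, featuretype="exon")), mrna.strand
            )
            cds_feats = _transcription_sort(
                list(db.children(mrna, featuretype="CDS")), mrna.strand
            )
            if not exon_feats:
                logger.warning("transcript %s has no exons; skipped", mrna.id)
                continue
            for prev, nxt in zip(exon_feats, exon_feats[1:]):
                lo, hi = sorted([prev, nxt], key=lambda f: f.start)
                if lo.end >= hi.start:
                    raise ValueError(
                        f"transcript {mrna.id}: overlapping exons "
                        f"{lo.start}-{lo.end} and {hi.start}-{hi.end}"
                    )
            cds_intervals = []
            for f in cds_feats:
                phase = 0 if f.frame in (".", "", None) else int(f.frame)
                cds_intervals.append((f.start, f.end, phase))
            first_phase = cds_intervals[0][2] if cds_intervals else 0
            coding_nt = sum(e - s + 1 for s, e, _ in cds_intervals) - first_phase
            if cds_intervals and coding_nt % 3 != 0:
                logger.warning(
                    "transcript %s: CDS length %d not divisible by 3 after "
                    "phase adjustment; transcript skipped",
                    mrna.id,
                    coding_nt,
                )
                continue

            classes = _classify_positions(len(exon_feats))
            exons = []
            for feat, cls in zip(exon_feats, classes):
                coding = sum(
                    max(0, min(feat.end, ce) - max(feat.start, cs) + 1)
                    for cs, ce, _ in cds_intervals
                )
                exons.append(Exon(feat.start, feat.end, cls, coding))

            protein_id = mrna.attributes.get("protein_id", [None])[0]
            if protein_id is None and cds_feats:
                protein_id = cds_feats[0].attributes.get("protein_id", [None])[0]
            transcripts.append(
                Transcript(
                    transcript_id=mrna.id,
                    protein_id=protein_id or mrna.id,
                    strand=mrna.strand,
                    exons=exons,
                    cds_intervals=cds_intervals,
                    seqid=mrna.seqid,
                )
            )
        if transcripts:
            genes.append(
                GeneModel(
                    gene_id=gene.id,
                    strand=gene.strand,
                    transcripts=transcripts,
                    seqid=gene.seqid,
                )
            )
    return genes


# ---------------------------------------------------------------------------
# Exon -> residue mapping
# ---------------------------------------------------------------------------


def map_exons_to_residues(
    transcript: Transcript, cds_includes_stop: bool = True
) -> list[ExonResidueMap]:
    """Map each coding exon to the protein residue interval it encodes.

    The CDS pieces are concatenated in transcription order (the phase
    overhang of the first piece is discarded) and numbered 1..N.  Codon c
    occupies nucleotides 3c-2..3c; its residue is attributed to the piece
    holding at least two of those three nucleotides.  The stop codon is
    dropped when ``cds_includes_stop`` (residue annotations never cover it).
    Exons contributing no residue under the majority rule yield no map.
    """
    if not transcript.cds_intervals:
        return []
    protein_len = transcript.protein_length(cds_includes_stop)
    if protein_len < 1:
        return []

    # coding-nt span [a, b] of each CDS piece after skipping the first phase
    first_phase = transcript.cds_intervals[0][2]
    spans: list[tuple[int, int, tuple[int, int]]] = []
    pos = 0
    for i, (s, e, _ph) in enumerate(transcript.cds_intervals):
        length = e - s + 1 - (first_phase if i == 0 else 0)
        if length <= 0:
            continue
        spans.append((pos + 1, pos + length, (s, e)))
        pos += length

    exon_by_cds: dict[tuple[int, int], Exon] = {}
    for exon in transcript.exons:
        for s, e, _ph in transcript.cds_intervals:
            if exon.genomic_start <= s and e <= exon.genomic_end:
                exon_by_cds[(s, e)] = exon

    maps: list[ExonResidueMap] = []
    for a, b, cds_key in spans:
        c_a = (a - 1) // 3 + 1  # codon containing nt a
        first = c_a if min(b, 3 * c_a) - a + 1 >= 2 else c_a + 1
        c_b = (b - 1) // 3 + 1  # codon containing nt b
        last = c_b if b - max(a, 3 * c_b - 2) + 1 >= 2 else c_b - 1
        last = min(last, protein_len)
        if first > last:
            continue
        exon = exon_by_cds.get(cds_key)
        if exon is None:  # CDS not nested in any exon; tolerate
            logger.warning(
                "transcript %s: CDS %s not contained in an exon",
                transcript.transcript_id,
                cds_key,
            )
            continue
        maps.append(ExonResidueMap(exon, first, last))
    return maps


# ---------------------------------------------------------------------------
# Deduplication across transcript variants
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InternalExonRecord:
    """A nonredundant internal exon with its residue map (if coding)."""

    gene_id: str
    transcript_id: str
    protein_id: str
    exon: Exon
    first_residue: int | None
    last_residue: int | None

    @property
    def y(self) -> int | None:
        if self.first_residue is None:
            return None
        return self.last_residue - self.first_residue + 1

    @property
    def nt_length(self) -> int:
        return self.exon.nt_length


def deduplicate_internal_exons(
    gene: GeneModel, cds_includes_stop: bool = True
) -> list[InternalExonRecord]:
    """Collapse a gene's internal exons to one record per genomic interval.

    An exon internal in at least one transcript variant is treated as
    internal (inclusive rule).  The residue map of the first transcript in
    which the exon appears as internal is kept.  Idempotent by construction:
    records are keyed on (start, end), which deduplication does not alter.
    """
    seen: dict[tuple[int, int], InternalExonRecord] = {}
    mixed: set[tuple[int, int]] = set()
    terminal_seen: set[tuple[int, int]] = set()
    for t in gene.transcripts:
        residue_maps = {m.exon_ref.key: m for m in map_exons_to_residues(t, cds_includes_stop)}
        for exon in t.exons:
            if exon.position_class != "internal":
                terminal_seen.add(exon.key)
                continue
            if exon.key in seen:
                continue
            m = residue_maps.get(exon.key)
            seen[exon.key] = InternalExonRecord(
                gene_id=gene.gene_id,
                transcript_id=t.transcript_id,
                protein_id=t.protein_id,
                exon=exon,
                first_residue=m.first_residue if m else None,
                last_residue=m.last_residue if m else None,
            )
    mixed = terminal_seen & set(seen)
    if mixed:
        logger.info(
            "gene %s: %d exon(s) internal in one variant and terminal in "
            "another; classified internal",
            gene.gene_id,
            len(mixed),
        )
    return sorted(seen.values(), key=lambda r: r.exon.key)


def nonredundant_internal_exons(
    genes: Iterable[GeneModel], cds_includes_stop: bool = True
) -> list[InternalExonRecord]:
    """Pool deduplicated internal exons over a collection of genes."""
    records: list[InternalExonRecord] = []
    for gene in genes:
        records.extend(deduplicate_internal_exons(gene, cds_includes_stop))
    return records


# ---------------------------------------------------------------------------
# Nucleotide composition
# ---------------------------------------------------------------------------


def cytidine_fraction(exon: Exon, contig_seq: str, strand: str = "+") -> float:
    """Fraction of cytidine on the coding strand of an exon.

    Ambiguous nucleotides contribute to the denominator only.
    """
    if exon.genomic_end > len(contig_seq):
        raise ValueError("genomic sequence does not cover the exon")
    seq = contig_seq[exon.genomic_start - 1 : exon.genomic_end]
    if strand == "-":
        seq = reverse_complement(seq)
    return seq.upper().count("C") / len(seq)


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

EXON_TABLE_COLUMNS = [
    "gene_id",
    "transcript_ids",
    "seqid",
    "genomic_start",
    "genomic_end",
    "position_class",
    "nt_length",
    "first_residue",
    "last_residue",
]


def exon_table(genes: Iterable[GeneModel], cds_includes_stop: bool = True):
    """Nonredundant internal-exon table as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for gene in genes:
        carriers: dict[tuple[int, int], list[str]] = {}
        for t in gene.transcripts:
            for exon in t.exons:
                carriers.setdefault(exon.key, []).append(t.transcript_id)
        for rec in deduplicate_internal_exons(gene, cds_includes_stop):
            rows.append(
                {
                    "gene_id": rec.gene_id,
                    "transcript_ids": ",".join(carriers[rec.exon.key]),
                    "seqid": gene.seqid,
                    "genomic_start": rec.exon.genomic_start,
                    "genomic_end": rec.exon.genomic_end,
                    "position_class": "internal",
                    "nt_length": rec.nt_length,
                    "first_residue": rec.first_residue,
                    "last_residue": rec.last_residue,
                }
            )
    return pd.DataFrame(rows, columns=EXON_TABLE_COLUMNS)
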