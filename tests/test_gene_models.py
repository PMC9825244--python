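import textwrap

import pytest

from exarch.gene_models import (
    Exon,
    Transcript,
    cytidine_fraction,
    deduplicate_internal_exons,
    map_exons_to_residues,
    nonredundant_internal_exons,
    read_gene_models,
)
from exarch.simulate import internal_exon_records, to_gene_models


def _transcript(exon_lengths, starts=None, strand="+"):
    """Fully coding single-strand transcript on a toy contig."""
    exons, cds = [], []
    pos = 100
    n = len(exon_lengths)
    classes = (
        ["single"]
        if n == 1
        else ["first_terminal"] + ["internal"] * (n - 2) + ["last_terminal"]
    )
    cum = 0
    for ln, cls in zip(exon_lengths, classes):
        s, e = pos + 1, pos + ln
        exons.append(Exon(s, e, cls, ln))
        cds.append((s, e, (3 - cum % 3) % 3))
        cum += ln
        pos = e + 50
    return Transcript("t1", "p1", strand, exons, cds, seqid="chr1")


class TestReadGeneModels:
    def test_three_exon_forward_gene_classes(self, three_exon_gff):
        genes = read_gene_models(three_exon_gff)
        assert len(genes) == 1
        classes = [e.position_class for e in genes[0].transcripts[0].exons]
        assert classes == ["first_terminal", "internal", "last_terminal"]

    def test_reverse_strand_gives_identical_classes(self, reverse_three_exon_gff):
        genes = read_gene_models(reverse_three_exon_gff)
        t = genes[0].transcripts[0]
        assert [e.position_class for e in t.exons] == [
            "first_terminal",
            "internal",
            "last_terminal",
        ]
        # transcription order: first exon has the highest coordinates
        assert t.exons[0].genomic_start == 801

    def test_two_exon_gene_has_no_internal(self, tmp_path):
        gff = textwrap.dedent(
            """\
            ##gff-version 3
            chr1\tt\tgene\t101\t402\t.\t+\t.\tID=g
            chr1\tt\tmRNA\t101\t402\t.\t+\t.\tID=g.t;Parent=g
            chr1\tt\texon\t101\t202\t.\t+\t.\tID=e1;Parent=g.t
            chr1\tt\texon\t301\t402\t.\t+\t.\tID=e2;Parent=g.t
            chr1\tt\tCDS\t101\t202\t.\t+\t0\tID=c;Parent=g.t
            chr1\tt\tCDS\t301\t402\t.\t+\t0\tID=c;Parent=g.t
            """
        )
        p = tmp_path / "two.gff3"
        p.write_text(gff)
        genes = read_gene_models(str(p))
        classes = [e.position_class for e in genes[0].transcripts[0].exons]
        assert "internal" not in classes

    def test_bad_cds_length_skips_transcript(self, tmp_path, caplog):
        gff = textwrap.dedent(
            """\
            ##gff-version 3
            chr1\tt\tgene\t101\t400\t.\t+\t.\tID=g
            chr1\tt\tmRNA\t101\t400\t.\t+\t.\tID=g.t;Parent=g
            chr1\tt\texon\t101\t200\t.\t+\t.\tID=e1;Parent=g.t
            chr1\tt\texon\t301\t402\t.\t+\t.\tID=e2;Parent=g.t
            chr1\tt\tCDS\t101\t200\t.\t+\t0\tID=c;Parent=g.t
            chr1\tt\tCDS\t301\t402\t.\t+\t2\tID=c;Parent=g.t
            """
        )
        p = tmp_path / "bad.gff3"
        p.write_text(gff)
        import logging

        with caplog.at_level(logging.WARNING, logger="exarch"):
            genes = read_gene_models(str(p))
        assert genes == []
        assert any("not divisible" in r.message for r in caplog.records)


class TestResidueMapping:
    def test_single_exon_cds_excludes_stop(self):
        t = _transcript([303])
        maps = map_exons_to_residues(t)
        assert len(maps) == 1
        assert (maps[0].first_residue, maps[0].last_residue) == (1, 100)

    def test_split_codon_one_two_goes_to_second_exon(self):
        # codon 34 split 1|2 across a 100/203 junction
        t = _transcript([100, 203])
        maps = map_exons_to_residues(t)
        spans = [(m.first_residue, m.last_residue) for m in maps]
        assert spans == [(1, 33), (34, 100)]

    def test_split_codon_two_one_goes_to_first_exon(self):
        # codon 34 split 2|1 across a 101/202 junction
        t = _transcript([101, 202])
        maps = map_exons_to_residues(t)
        spans = [(m.first_residue, m.last_residue) for m in maps]
        assert spans == [(1, 34), (35, 100)]

    @pytest.mark.parametrize("lengths", [[303], [100, 203], [90, 90, 123], [47, 85, 100, 71]])
    def test_maps_partition_protein(self, lengths):
        t = _transcript(lengths)
        maps = map_exons_to_residues(t)
        covered = []
        for m in maps:
            covered.extend(range(m.first_residue, m.last_residue + 1))
        assert covered == list(range(1, t.protein_length() + 1))

    def test_partition_holds_for_all_synthetic_transcripts(self, small_archs):
        for gene in to_gene_models(small_archs):
            for t in gene.transcripts:
                maps = map_exons_to_residues(t)
                covered = []
                for m in sorted(maps, key=lambda m: m.first_residue):
                    covered.extend(range(m.first_residue, m.last_residue + 1))
                assert covered == list(range(1, t.protein_length() + 1))


class TestDeduplication:
    def _two_variant_gene(self):
        from exarch.gene_models import GeneModel

        t1 = _transcript([100, 203, 90])
        # variant sharing the internal exon but with a different last exon
        t2 = Transcript(
            "t2",
            "p1",
            "+",
            [
                t1.exons[0],
                t1.exons[1],
                Exon(t1.exons[2].genomic_start + 200, t1.exons[2].genomic_end + 200,
                     "last_terminal", 90),
            ],
            t1.cds_intervals,
            seqid="chr1",
        )
        return GeneModel("g", "+", [t1, t2], seqid="chr1")

    def test_shared_internal_exon_counted_once(self):
        gene = self._two_variant_gene()
        recs = deduplicate_internal_exons(gene)
        assert len(recs) == 1

    def test_idempotent(self):
        gene = self._two_variant_gene()
        once = deduplicate_internal_exons(gene)
        again = deduplicate_internal_exons(gene)
        assert [(r.exon.key, r.first_residue, r.last_residue) for r in once] == [
            (r.exon.key, r.first_residue, r.last_residue) for r in again
        ]

    def test_exon_internal_in_one_variant_is_internal(self, small_archs):
        # genes with a UTR-bearing variant expose their first coding exon as
        # internal; the inclusive rule keeps it
        genes = to_gene_models(small_archs)
        utr_genes = [a for a in small_archs if a.utr_variant]
        assert utr_genes, "fixture should contain at least one UTR variant"
        by_id = {g.gene_id: g for g in genes}
        for arch in utr_genes:
            recs = deduplicate_internal_exons(by_id[arch.gene_id])
            keys = {r.exon.key for r in recs}
            assert tuple(arch.exon_coords[0]) in keys

    def test_generator_records_match_pipeline_records(self, small_archs):
        mem = internal_exon_records(small_archs)
        pipe = nonredundant_internal_exons(to_gene_models(small_archs))
        key = lambda r: (r.gene_id, r.exon.key, r.first_residue, r.last_residue)
        assert sorted(map(key, mem)) == sorted(map(key, pipe))


class TestCytidine:
    @pytest.mark.parametrize(
        "seq,expected",
        [("CCCC", 1.0), ("ATGA", 0.0), ("ACGTACGT", 0.25)],
    )
    def test_plus_strand_counts(self, seq, expected):
        exon = Exon(1, len(seq), "internal", len(seq))
        assert cytidine_fraction(exon, seq) == expected

    def test_minus_strand_counts_complement(self):
        # coding strand C corresponds to genomic G on the plus strand
        exon = Exon(1, 4, "internal", 4)
        assert cytidine_fraction(exon, "GGGG", strand="-") == 1.0

    def test_ambiguous_in_denominator_only(self):
        exon = Exon(1, 4, "internal", 4)
        assert cytidine_fraction(exon, "CCNN") == 0.5
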