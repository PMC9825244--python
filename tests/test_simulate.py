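import hashlib
import json

import numpy as np
import pytest

from exarch.gene_models import read_gene_models, nonredundant_internal_exons
from exarch.annotations import read_interval_table
from exarch.insertions import detect_lineage_insertions
from exarch.simulate import (
    GeneratorConfig,
    generate_genome,
    generate_ortholog_trios,
    internal_exon_records,
    sample_genome,
)


def _hash(path):
    return hashlib.sha256(open(path, "rb").read()).hexdigest()


class TestGeneratorValidity:
    def test_invalid_config_rejected_before_emission(self):
        with pytest.raises(ValueError):
            GeneratorConfig(long_weight=1.5).validate()
        with pytest.raises(ValueError):
            GeneratorConfig(idr_coupling_beta=-0.1).validate()
        with pytest.raises(ValueError):
            GeneratorConfig(host_restriction="constrained_only").validate()

    def test_emitted_files_round_trip_cleanly(self, emitted_genome, small_archs):
        genes = read_gene_models(emitted_genome["gff3"])
        assert len(genes) == len(small_archs)
        file_recs = nonredundant_internal_exons(genes)
        mem_recs = internal_exon_records(small_archs)
        key = lambda r: (r.gene_id, r.exon.key, r.first_residue, r.last_residue)
        assert sorted(map(key, file_recs)) == sorted(map(key, mem_recs))

    def test_annotations_within_protein_bounds(self, emitted_genome, small_archs):
        lengths = {a.protein_id: a.protein_len for a in small_archs}
        for kind, path in (("IDR", emitted_genome["idr"]), ("DOMAIN", emitted_genome["domains"])):
            anns = read_interval_table(path, kind, protein_lengths=lengths)
            for ann in anns:
                assert ann.intervals[-1][1] <= lengths[ann.protein_id]

    def test_domains_contain_their_anchor_exons(self, small_archs):
        for arch in small_archs:
            anchored_spans = [arch.spans[i] for i in arch.anchor_idx]
            for f, l in anchored_spans:
                assert any(ds <= f and l <= de for ds, de in arch.domains)

    def test_truth_file_consistent(self, emitted_genome, small_archs):
        truth = json.load(open(emitted_genome["truth"]))
        assert len(truth["genes"]) == len(small_archs)
        by_id = {g["gene_id"]: g for g in truth["genes"]}
        for arch in small_archs:
            assert by_id[arch.gene_id]["exon_nt"] == arch.exon_nt


class TestDeterminism:
    def test_same_seed_same_architecture(self, small_config):
        a = sample_genome(small_config, 5)
        b = sample_genome(small_config, 5)
        assert [x.exon_nt for x in a] == [x.exon_nt for x in b]
        assert [x.idr_intervals for x in a] == [x.idr_intervals for x in b]
        assert [x.domains for x in a] == [x.domains for x in b]

    def test_byte_identical_reruns(self, tmp_path, small_config):
        p1 = generate_genome(small_config, str(tmp_path / "a"), 3)
        p2 = generate_genome(small_config, str(tmp_path / "b"), 3)
        for k in p1:
            assert _hash(p1[k]) == _hash(p2[k]), k

    def test_different_seeds_differ(self, small_config):
        a = sample_genome(small_config, 1)
        b = sample_genome(small_config, 2)
        assert [x.exon_nt for x in a] != [x.exon_nt for x in b]


class TestNullGenome:
    def test_zero_coupling_gives_near_zero_correlation_over_seeds(self):
        from exarch.idr_analysis import exon_idr_table
        from exarch.simulate import idr_annotations
        from exarch.stats import correlation_t_test

        cfg = GeneratorConfig(n_genes=80, idr_coupling_beta=0.0)
        rng = np.random.default_rng(17)
        rs = []
        for _ in range(25):
            archs = sample_genome(cfg, rng)
            tab = exon_idr_table(
                internal_exon_records(archs), idr_annotations(archs)
            ).dropna()
            rs.append(correlation_t_test(tab["nt_length"], tab["idr_fraction"]).r)
        assert abs(float(np.mean(rs))) < 0.03


class TestTrios:
    def test_zero_planted_insertions_detected_as_empty(self):
        cfg = GeneratorConfig.trio_defaults(
            trio_n_genes=10, n_within_insertions=0, n_whole_insertions=0
        )
        ts = generate_ortholog_trios(cfg, 2)
        for aln in ts.alignments:
            assert detect_lineage_insertions(aln, "lineage1") == []
            assert detect_lineage_insertions(aln, "lineage2") == []

    def test_plan_counts_met_exactly(self):
        cfg = GeneratorConfig.trio_defaults(
            trio_n_genes=40, n_within_insertions=12, n_whole_insertions=5
        )
        ts = generate_ortholog_trios(cfg, 2)
        assert sum(not t.whole_exon for t in ts.truth) == 12
        assert sum(t.whole_exon for t in ts.truth) == 5

    def test_alignments_ungap_to_protein_sequences(self):
        cfg = GeneratorConfig.trio_defaults(trio_n_genes=15, n_within_insertions=5,
                                            n_whole_insertions=2)
        ts = generate_ortholog_trios(cfg, 4)
        for aln in ts.alignments:
            assert aln.ungapped("lineage1") == ts.protein_seqs[aln.lineage1_id]
            assert aln.ungapped("lineage2") == ts.protein_seqs[aln.lineage2_id]
            assert aln.ungapped("outgroup") == ts.protein_seqs[aln.outgroup_id]

    def test_infeasible_plan_rejected(self):
        cfg = GeneratorConfig.trio_defaults(
            trio_n_genes=5, n_within_insertions=10, n_whole_insertions=0
        )
        with pytest.raises(ValueError):
            generate_ortholog_trios(cfg, 1)
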