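import pytest

from exarch.accretion import (
    DomainSegment,
    candidate_exons,
    extract_segments,
    gene_segments,
    longest_exon_by_distance_bin,
)
from exarch.annotations import IntervalAnnotation
from exarch.gene_models import Exon, ExonResidueMap
from exarch.simulate import domain_annotations, to_gene_models


def _dom(*ivs):
    return IntervalAnnotation("p", "SCOP", "DOMAIN", tuple(ivs))


def _map(first, last, cls="internal", nt=None):
    nt = nt if nt is not None else 3 * (last - first + 1)
    return ExonResidueMap(Exon(first * 10, first * 10 + nt - 1, cls, nt), first, last)


class TestExtractSegments:
    def test_three_domains_give_two_a_and_one_b(self):
        segs = extract_segments("g", _dom((1, 50), (100, 150), (200, 260)), 400)
        groups = [s.group for s in segs]
        assert groups == ["A", "A", "B"]
        assert (segs[0].span_start, segs[0].span_end) == (51, 99)
        assert (segs[2].span_start, segs[2].span_end) == (261, 400)

    def test_single_domain_gives_group_b_only(self):
        segs = extract_segments("g", _dom((10, 60)), 200)
        assert [s.group for s in segs] == ["B"]

    def test_domainless_gene_is_an_error(self):
        with pytest.raises(ValueError):
            extract_segments("g", _dom(), 100)


class TestCandidateRules:
    def test_exon_encoding_upstream_domain_cterm_is_group_a_candidate(self):
        seg = DomainSegment("A", "g", 101, 199, upstream_domain_end=100,
                            downstream_domain_start=200)
        m = _map(95, 110)
        assert candidate_exons(seg, [m]) == [(m.exon_ref, 95)]

    def test_exon_starting_between_domains_is_group_a_candidate(self):
        seg = DomainSegment("A", "g", 101, 199, upstream_domain_end=100,
                            downstream_domain_start=200)
        m = _map(105, 130)
        assert candidate_exons(seg, [m]) == [(m.exon_ref, 105)]

    def test_exon_inside_upstream_domain_is_not_a_candidate(self):
        seg = DomainSegment("A", "g", 101, 199, upstream_domain_end=100,
                            downstream_domain_start=200)
        assert candidate_exons(seg, [_map(40, 80)]) == []

    def test_group_b_requires_last_residue_downstream_of_domain(self):
        seg = DomainSegment("B", "g", 101, 300, upstream_domain_end=100,
                            downstream_domain_start=None)
        inside = _map(40, 90)
        after = _map(95, 120)
        assert candidate_exons(seg, [inside]) == []
        assert candidate_exons(seg, [after]) == [(after.exon_ref, 95)]

    def test_terminal_exons_never_candidates(self):
        seg = DomainSegment("B", "g", 101, 300, upstream_domain_end=100,
                            downstream_domain_start=None)
        assert candidate_exons(seg, [_map(90, 200, cls="last_terminal")]) == []

    def test_candidates_agree_with_literal_rule_on_synthetic_genes(self, small_archs):
        from exarch.gene_models import map_exons_to_residues

        doms = domain_annotations(small_archs)
        for gene in to_gene_models(small_archs):
            ann = doms.get(gene.transcripts[0].protein_id)
            if ann is None:
                continue
            for seg in gene_segments(gene, doms):
                maps = map_exons_to_residues(gene.transcripts[0])
                literal = set()
                for m in maps:
                    if m.exon_ref.position_class != "internal":
                        continue
                    if seg.group == "A":
                        if (
                            m.first_residue <= seg.upstream_domain_end <= m.last_residue
                            or seg.upstream_domain_end < m.first_residue < seg.downstream_domain_start
                        ):
                            literal.add(m.exon_ref.key)
                    elif m.last_residue > seg.upstream_domain_end:
                        literal.add(m.exon_ref.key)
                # gene_segments unions candidates over variants; the primary
                # transcript's literal candidates must all be present
                got = {e.key for e, _ in seg.candidates}
                assert literal <= got


class TestLongestByDistance:
    def _seg(self, group, dist_res, longest_nts):
        seg = DomainSegment(group, "g", 1, dist_res, upstream_domain_end=0,
                            downstream_domain_start=None if group == "B" else dist_res + 1)
        for i, nt in enumerate(longest_nts):
            seg.candidates.append((Exon(1000 * (i + 1), 1000 * (i + 1) + nt - 1, "internal", nt), i + 1))
        return seg

    def test_bin_requires_min_n_in_both_groups(self):
        segs = [self._seg("A", 50, [120]) for _ in range(30)]
        segs += [self._seg("B", 50, [100]) for _ in range(20)]
        assert longest_exon_by_distance_bin(segs, min_n=25) == []

    def test_tie_broken_by_five_prime_most(self):
        seg = self._seg("A", 50, [120, 480, 480])
        assert seg.longest_exon_nt == 480
        best = min(seg.candidates, key=lambda c: (-c[0].nt_length, c[1]))
        assert best[1] == 2  # first of the tied exons in transcription order

    def test_reported_bins_have_means(self):
        segs = [self._seg("A", 50, [300]) for _ in range(30)]
        segs += [self._seg("B", 50, [100]) for _ in range(30)]
        rows = longest_exon_by_distance_bin(segs, min_n=25)
        means = {r["group"]: r["mean_longest_nt"] for r in rows}
        assert means["A"] == pytest.approx(300)
        assert means["B"] == pytest.approx(100)

    def test_segments_without_candidates_excluded(self):
        segs = [self._seg("A", 50, []) for _ in range(40)]
        segs += [self._seg("B", 50, [100]) for _ in range(40)]
        assert longest_exon_by_distance_bin(segs, min_n=25) == []
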