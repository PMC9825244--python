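import textwrap

import numpy as np
import pytest

from exarch.simulate import (
    GeneratorConfig,
    generate_genome,
    sample_genome,
)


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(n_genes=40)


@pytest.fixture(scope="session")
def small_archs(small_config):
    return sample_genome(small_config, 11)


@pytest.fixture(scope="session")
def emitted_genome(tmp_path_factory, small_config):
    outdir = tmp_path_factory.mktemp("genome")
    paths = generate_genome(small_config, str(outdir), 11)
    return paths


@pytest.fixture()
def three_exon_gff(tmp_path):
    """Forward-strand 3-exon gene, fully coding, 303 nt CDS (100 aa + stop)."""
    gff = textwrap.dedent(
        """\
        ##gff-version 3
        chr1\ttest\tgene\t101\t900\t.\t+\t.\tID=gA
        chr1\ttest\tmRNA\t101\t900\t.\t+\t.\tID=gA.t1;Parent=gA;protein_id=pA
        chr1\ttest\texon\t101\t200\t.\t+\t.\tID=gA.t1.e1;Parent=gA.t1
        chr1\ttest\texon\t301\t403\t.\t+\t.\tID=gA.t1.e2;Parent=gA.t1
        chr1\ttest\texon\t801\t900\t.\t+\t.\tID=gA.t1.e3;Parent=gA.t1
        chr1\ttest\tCDS\t101\t200\t.\t+\t0\tID=cA;Parent=gA.t1
        chr1\ttest\tCDS\t301\t403\t.\t+\t2\tID=cA;Parent=gA.t1
        chr1\ttest\tCDS\t801\t900\t.\t+\t1\tID=cA;Parent=gA.t1
        """
    )
    path = tmp_path / "three_exon.gff3"
    path.write_text(gff)
    return str(path)


@pytest.fixture()
def reverse_three_exon_gff(tmp_path):
    """The same gene mirrored onto the minus strand of a 1000-nt contig."""
    # mirror of [101,200],[301,403],[801,900] on length 1000
    gff = textwrap.dedent(
        """\
        ##gff-version 3
        chr1\ttest\tgene\t101\t900\t.\t-\t.\tID=gA
        chr1\ttest\tmRNA\t101\t900\t.\t-\t.\tID=gA.t1;Parent=gA;protein_id=pA
        chr1\ttest\texon\t801\t900\t.\t-\t.\tID=gA.t1.e1;Parent=gA.t1
        chr1\ttest\texon\t598\t700\t.\t-\t.\tID=gA.t1.e2;Parent=gA.t1
        chr1\ttest\texon\t101\t200\t.\t-\t.\tID=gA.t1.e3;Parent=gA.t1
        chr1\ttest\tCDS\t801\t900\t.\t-\t0\tID=cA;Parent=gA.t1
        chr1\ttest\tCDS\t598\t700\t.\t-\t2\tID=cA;Parent=gA.t1
        chr1\ttest\tCDS\t101\t200\t.\t-\t1\tID=cA;Parent=gA.t1
        """
    )
    path = tmp_path / "reverse.gff3"
    path.write_text(gff)
    return str(path)
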