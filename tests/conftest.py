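"""Shared fixtures: small in-memory genotype matrices and on-disk format
fixtures written programmatically at test time."""

from __future__ import annotations

import textwrap

import numpy as np
import pytest

from germpop import GenotypeMatrix, Locus, PopulationMap


def make_matrix(calls, chrom="A01", depths=None, samples=None,
                positions=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a nested list of dosages (-1 = missing)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_loci = calls.shape
    if depths is None:
        depths = np.full(calls.shape, 10, dtype=np.int32)
    if samples is None:
        samples = [f"S{i}" for i in range(n_samples)]
    if positions is None:
        positions = [100 * (j + 1) for j in range(n_loci)]
    alleles = [("A", "G"), ("C", "T"), ("G", "C"), ("T", "A")]
    loci = [Locus(chrom, positions[j], *alleles[j % 4]) for j in range(n_loci)]
    return GenotypeMatrix(samples=samples, loci=loci, calls=calls, depths=depths)


@pytest.fixture
def two_group_popmap():
    return PopulationMap({"S0": "g1", "S1": "g1", "S2": "g2", "S3": "g2"})


@pytest.fixture
def small_vcf(tmp_path):
    """3 samples, 2 good SNPs, one multi-allelic, one indel, mixed DP/GT."""
    text = textwrap.dedent("""\
        ##fileformat=VCFv4.2
        ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
        ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
        ##contig=<ID=A01>
        #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
        A01\t100\t.\tA\tG\t.\t.\t.\tGT:DP\t0/0:10\t0/1:8\t1/1:12
        A01\t200\t.\tC\tT\t.\t.\t.\tGT:DP\t./.:0\t0/1:3\t0/.:9
        A01\t300\t.\tG\tA,T\t.\t.\t.\tGT:DP\t0/0:9\t0/1:9\t0/2:9
        A01\t400\t.\tGA\tG\t.\t.\t.\tGT:DP\t0/0:9\t0/1:9\t1/1:9
        """)
    path = tmp_path / "small.vcf"
    path.write_text(text)
    return path


@pytest.fixture
def toy_gff3(tmp_path):
    """One plus-strand gene (2 exons, CDS spanning both) and one minus-strand
    gene, plus a CDS with an unknown parent."""
    text = textwrap.dedent("""\
        ##gff-version 3
        A01\tsrc\tgene\t101\t400\t.\t+\t.\tID=gene1
        A01\tsrc\tmRNA\t101\t400\t.\t+\t.\tID=tx1;Parent=gene1
        A01\tsrc\texon\t101\t200\t.\t+\t.\tParent=tx1
        A01\tsrc\texon\t301\t400\t.\t+\t.\tParent=tx1
        A01\tsrc\tCDS\t151\t200\t.\t+\t0\tParent=tx1
        A01\tsrc\tCDS\t301\t350\t.\t+\t2\tParent=tx1
        A01\tsrc\tfive_prime_UTR\t101\t150\t.\t+\t.\tParent=tx1
        A01\tsrc\tthree_prime_UTR\t351\t400\t.\t+\t.\tParent=tx1
        A01\tsrc\tgene\t1001\t1300\t.\t-\t.\tID=gene2
        A01\tsrc\tmRNA\t1001\t1300\t.\t-\t.\tID=tx2;Parent=gene2
        A01\tsrc\texon\t1001\t1300\t.\t-\t.\tParent=tx2
        A01\tsrc\tCDS\t1051\t1250\t.\t-\t0\tParent=tx2
        A01\tsrc\tCDS\t9001\t9100\t.\t+\t0\tParent=ghost_tx
        """)
    path = tmp_path / "toy.gff3"
    path.write_text(text)
    return path
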