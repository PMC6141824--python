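import numpy as np
import pandas as pd
import pytest

from coldqtl.triage import GeneModel


@pytest.fixture
def wide_counts():
    """Tiny wide-format count table covering the definitional corner cases."""
    return pd.DataFrame({
        "chrom": ["chr1"] * 4,
        "pos": [100, 200, 300, 400],
        "high_ref": [2, 20, 0, 5],
        "high_alt": [8, 0, 15, 5],
        "low_ref": [18, 20, 15, 5],
        "low_alt": [2, 0, 0, 5],
    })


@pytest.fixture
def plus_gene():
    """5-codon plus-strand gene: ATG AAA TTT CCC TAA at chr pos 11..25."""
    return GeneModel(gene_id="GENE_P", chrom="chrT", strand="+", cds=((11, 25),))


@pytest.fixture
def toy_genome():
    #           1234567890 ATG AAA TTT CCC TAA 6789012345
    seq = "GGGGGGGGGG" + "ATGAAATTTCCCTAA" + "GGGGGGGGGG"
    return {"chrT": seq}


def write_toy_annotation(tmp_path, cds_len_plus=15):
    """Write a 2-gene GFF3 (+ and - strand, the minus one with a split CDS)
    and a matching FASTA; returns (gff_path, fasta_path)."""
    # minus-strand gene: CDS pieces 41-49 and 53-58 (total 15, %3 == 0)
    seq = "GGGGGGGGGG" + "ATGAAATTTCCCTAA" + "GGGGGGGGGG" + "A" * 30
    fasta = tmp_path / "toy.fa"
    fasta.write_text(">chrT\n" + seq + "\n")
    gff = tmp_path / "toy.gff3"
    gff.write_text("\n".join([
        "##gff-version 3",
        "chrT\ttest\tgene\t11\t{}\t.\t+\t.\tID=GENE_P".format(10 + cds_len_plus),
        "chrT\ttest\tCDS\t11\t{}\t.\t+\t0\tID=cdsP;Parent=GENE_P".format(10 + cds_len_plus),
        "chrT\ttest\tgene\t41\t58\t.\t-\t.\tID=GENE_M",
        "chrT\ttest\tCDS\t41\t49\t.\t-\t0\tID=cdsM1;Parent=GENE_M",
        "chrT\ttest\tCDS\t53\t58\t.\t-\t0\tID=cdsM2;Parent=GENE_M",
        "",
    ]))
    return gff, fasta
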