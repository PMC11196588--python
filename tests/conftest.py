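import numpy as np
import pandas as pd
import pytest

from hevecore.genotype_io import LOCUS_COLUMNS, GenotypePanel


def make_panel(G, positions=None, chrom="chr1", sample_ids=None, DP=None):
    """Build a GenotypePanel from a plain genotype matrix for tests."""
    G = np.asarray(G, dtype=np.int8)
    n, m = G.shape
    if positions is None:
        positions = [(j + 1) * 100 for j in range(m)]
    loci = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "id": [f"L{j + 1}" for j in range(m)],
            "ref": "A",
            "alt": "G",
        },
        columns=LOCUS_COLUMNS,
    )
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n)]
    return GenotypePanel(sample_ids, loci, G, DP)


@pytest.fixture
def tiny_panel():
    """3 samples x 4 loci with one missing call."""
    return make_panel(
        [
            [0, 1, 2, 0],
            [1, 1, 0, 9],
            [2, 0, 0, 1],
        ]
    )


@pytest.fixture
def hand_vcf(tmp_path):
    """Handcrafted 3-sample, 2-locus VCF with known coding."""
    text = "\n".join(
        [
            "##fileformat=VCFv4.2",
            "##contig=<ID=chr1,length=2000>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC",
            "chr1\t100\tv1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1",
            "chr1\t200\tv2\tC\tT\t.\tPASS\t.\tGT\t1/0\t./.\t0/0",
        ]
    )
    path = tmp_path / "hand.vcf"
    path.write_text(text + "\n")
    return path
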