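import pytest

from trkfuse import fusionannot, synthdata

CHROM_NAMES = ("chr1", "chr7", "chr12", "chr15")

# mid-intron breakpoints in the packaged toy gene models
ETV6_INTRON5 = 7400
NTRK3_INTRON14 = 27080
LMNA_INTRON2 = 9840
NTRK1_INTRON10 = 35000
TPM3_INTRON7 = 5440
NTRK1_INTRON8 = 33960


@pytest.fixture(scope="session")
def toy_ref():
    return synthdata.make_reference(4, 50_000, seed=7, names=CHROM_NAMES)


@pytest.fixture(scope="session")
def gene_models():
    return fusionannot.load_gene_models()


@pytest.fixture(scope="session")
def model_by_name(gene_models):
    return {g.name: g for g in gene_models}
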