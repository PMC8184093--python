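import io
import textwrap

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from biblionet import bioentity as be
from biblionet.synthetic import fixture_path


MEDLINE_THREE = textwrap.dedent("""\
    PMID- 1001
    DP  - 2020 Jun
    TI  - Spike protein binding and viral entry mechanisms.
    AB  - The spike protein mediates receptor binding. Genes, genes, GENE.
    JT  - Journal of Testing
    AD  - Dept of X, University of Oxford, Oxford, UK.
    MH  - COVID-19

    DP  - 2020 Jul
    TI  - A record with no identifier that must be skipped.

    PMID- 1002
    DP  - 2021
    TI  - Spike protein structural analysis.
    AB  - Structural insight into the spike protein.
    JT  - Journal of Testing

""")


@pytest.fixture
def medline_stream():
    return io.StringIO(MEDLINE_THREE)


PUBTATOR_FIVE = textwrap.dedent("""\
    123|t|ACE2 and COVID-19.
    123|a|ACE2 binds the virus in COVID-19 patients carrying rs2285666.
    123\t0\t4\tACE2\tGene\t59272
    123\t9\t17\tCOVID-19\tDisease\tD000086382
    123\t70\t79\trs2285666\tSNP\trs2285666
    123\t20\t25\tvirus\tSpecies\t2697049
    123\tmalformed-line-without-proper-fields
    124|t|Remdesivir trial.
    124|a|Remdesivir with G8790A in influenza.
    124\t0\t10\tRemdesivir\tChemical\tC000606551
    124\t34\t40\tG8790A\tProteinMutation\tG8790A
    124\t44\t53\tinfluenza\tDisease\tD007251
    124\t54\t58\tAce2\tGene\t70008
""")


@pytest.fixture
def pubtator_stream():
    return io.StringIO(PUBTATOR_FIVE)


@pytest.fixture(scope="session")
def dictionaries():
    return (
        be.load_mesh_dict(fixture_path("mesh_descriptors.tsv")),
        be.load_gene_dict(fixture_path("human_genes.tsv")),
        be.load_snp_dict(fixture_path("snp_variants.tsv")),
    )
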