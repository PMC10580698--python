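import pytest

from mr2s.io import SummaryStatsTable, VariantAssociation


def make_variant(rsid="rs1", chrom="1", pos=100_000, ea="A", oa="G",
                 eaf=0.3, beta=0.1, se=0.02, pval=1e-10, n=10_000):
    return VariantAssociation(rsid=rsid, chrom=chrom, pos=pos,
                              effect_allele=ea, other_allele=oa, eaf=eaf,
                              beta=beta, se=se, pval=pval, n=n)


@pytest.fixture
def toy_table():
    """Three valid records on one chromosome."""
    return SummaryStatsTable(
        study_label="toy", trait="exposure",
        records=[
            make_variant("rs1", pos=100_000, beta=0.12, pval=1e-10),
            make_variant("rs2", pos=5_000_000, ea="T", oa="C", beta=-0.08, pval=3e-9),
            make_variant("rs3", chrom="2", pos=200_000, ea="C", oa="A", beta=0.10,
                         pval=4e-8, eaf=None, n=None),
        ],
    )
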