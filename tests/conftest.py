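import pytest

from clonarch import (
    AlterationType,
    AssayMode,
    Oncogenicity,
    SampleProfile,
    SomaticStatus,
    VariantCall,
)


def snv(
    gene="PIK3CA",
    af=0.1,
    pchange="H1047R",
    status=SomaticStatus.SOMATIC,
    ch=False,
    onc=Oncogenicity.KNOWN,
    mc=None,
    wc=None,
    alt_type=AlterationType.SNV,
):
    """Terse variant builder for tests."""
    return VariantCall(
        gene=gene,
        alteration_type=alt_type,
        protein_change=pchange,
        allele_fraction=af,
        somatic_status=status,
        ch_flag=ch,
        oncogenicity=onc,
        mutated_copies=mc,
        wildtype_copies=wc,
    )


def profile(variants, sample_id="S1", assay_mode=AssayMode.CTDNA, aneuploidy=None):
    return SampleProfile(
        sample_id=sample_id,
        assay_mode=assay_mode,
        variants=list(variants),
        aneuploidy_tumor_fraction=aneuploidy,
    )


@pytest.fixture
def variant_table(tmp_path):
    """3-row fixture table: 2 samples with 2 and 1 variants."""
    header = (
        "sample_id\tgene\talteration_type\tprotein_change\tallele_fraction\t"
        "somatic_status\tch_flag\toncogenicity\tmutated_copies\twildtype_copies"
    )
    rows = [
        "S1\tPIK3CA\tSNV\tH1047R\t0.12\tsomatic\t0\tknown\t.\t.",
        "S1\tTP53\tSNV\tR175H\t0.30\tsomatic\t0\tknown\t.\t.",
        "S2\tPIK3CA\tSNV\tE545K\t0.05\tsomatic\t0\tknown\t.\t.",
    ]
    path = tmp_path / "variants.tsv"
    path.write_text("\n".join([header, *rows]) + "\n")
    return path


@pytest.fixture
def clinical_table(tmp_path):
    header = "sample_id\tarm\tresponder\tpfs_months\tpfs_event\tvisceral_disease"
    rows = [
        "S1\texperimental\t1\t7.5\t1\tyes",
        "S2\tcontrol\t0\t3.2\t0\tno",
    ]
    path = tmp_path / "clinical.tsv"
    path.write_text("\n".join([header, *rows]) + "\n")
    return path
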