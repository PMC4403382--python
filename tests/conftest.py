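import pytest

from somascape import cnv_landscape, synth_cohort
from somascape.io_cohort import MutationCatalog, MutationRecord


@pytest.fixture(scope="session")
def profile():
    return synth_cohort.load_profile()


@pytest.fixture(scope="session")
def gene_model():
    return cnv_landscape.load_gene_model()


@pytest.fixture(scope="session")
def cohort109(profile):
    """One packaged-profile cohort shared by read-only tests."""
    return synth_cohort.generate_cohort(profile, seed=7)


@pytest.fixture(scope="session")
def cohort2000(profile):
    """Large cohort for frequency/effect recovery checks."""
    import dataclasses
    big = dataclasses.replace(profile, n_cases=2000)
    return synth_cohort.generate_cohort(big, seed=11)


def make_snv(case, gene, chrom, pos, ref, alt, vclass="missense",
             context3=None, **counts):
    defaults = dict(t_ref_count=30, t_alt_count=15, n_ref_count=30,
                    n_alt_count=0)
    defaults.update(counts)
    if context3 is None:
        context3 = "A" + ref + "A" if ref in "ACGT" and alt in "ACGT" else ""
    return MutationRecord(case_id=case, gene=gene, chrom=chrom, pos=pos,
                          ref=ref, alt=alt, variant_class=vclass,
                          context3=context3, **defaults)


@pytest.fixture
def tiny_catalog():
    """Three-case handmade catalog exercising spectra and burden paths."""
    records = [
        make_snv("C1", "KRAS", "12", 100, "C", "A", context3="ACA"),
        make_snv("C1", "TP53", "17", 200, "T", "C", context3="CTG"),
        make_snv("C1", "GENE1", "1", 300, "T", "C", context3="CTG"),
        make_snv("C1", "GENE2", "1", 400, "T", "C", context3="ATA"),
        make_snv("C2", "GENE3", "2", 500, "C", "T", vclass="silent",
                 context3="TCA"),
        make_snv("C2", "GENE4", "2", 600, "G", "T", context3="AGC"),
        MutationRecord(case_id="C2", gene="GENE5", chrom="3", pos=700,
                       ref="A", alt="-", variant_class="frame_shift_indel",
                       t_ref_count=20, t_alt_count=6, n_ref_count=20,
                       n_alt_count=0, context3=""),
    ]
    return MutationCatalog(records=records, case_roster=["C1", "C2", "C3"])
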