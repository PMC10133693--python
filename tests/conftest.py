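import textwrap

import pytest

from varprev.cohort_io import (
    ALL,
    AcmgCategory,
    CohortRow,
    CohortTable,
    CountUnit,
    DATA_DIR,
    PopulationCounts,
    read_summary_tsv,
)
from varprev.variants import (
    GenomicLocation,
    VariantRecord,
    infer_consequence,
    parse_hgvs_c,
    parse_hgvs_p,
)

GNOMAD_TSV = DATA_DIR / "gnomad_ttr_disease_causing.tsv"
CHINAMAP_TSV = DATA_DIR / "chinamap_ttr_disease_causing.tsv"
AMCARELAB_TSV = DATA_DIR / "amcarelab_ttr_pathogenic.tsv"


def make_record(cdna: str, protein: str | None = None, contig: str = "chr18",
                position: int | None = None) -> VariantRecord:
    """Build a variant record from HGVS strings; genomic key is synthetic."""
    c = parse_hgvs_c(cdna)
    p = parse_hgvs_p(protein) if protein else None
    location = None
    if position is not None and c.ref is not None:
        location = GenomicLocation(contig, position, c.ref, c.alt)
    rec = VariantRecord(location=location, transcript="NM_000371.4",
                        protein_id="NP_000362.1", cdna=c, protein=p)
    rec.consequence = infer_consequence(rec)
    return rec


def make_row(cdna: str, protein: str | None = None, allele_count: int = 1,
             homozygote_count: int = 0, population: str = ALL,
             cohort_individuals: int | None = None,
             position: int | None = None) -> CohortRow:
    rec = make_record(cdna, protein, position=position)
    counts = PopulationCounts(population=population, allele_count=allele_count,
                              homozygote_count=homozygote_count,
                              cohort_individuals=cohort_individuals)
    return CohortRow(record=rec, counts={population: counts})


@pytest.fixture
def gnomad_table() -> CohortTable:
    return read_summary_tsv(GNOMAD_TSV, "gnomad_like", database_name="gnomAD",
                            cohort_individuals=125780)


@pytest.fixture
def chinamap_table() -> CohortTable:
    return read_summary_tsv(CHINAMAP_TSV, "chinamap_like", database_name="ChinaMAP",
                            cohort_individuals=10588)


@pytest.fixture
def amcarelab_table() -> CohortTable:
    return read_summary_tsv(AMCARELAB_TSV, "clinical_exome_like",
                            database_name="Amcarelab", cohort_individuals=45392)


@pytest.fixture
def mixed_consequence_table() -> CohortTable:
    """Synthetic table exercising every consequence class the filter removes."""
    rows = [
        make_row("c.148G>A", "p.V50M", allele_count=26, position=29172937),
        make_row("c.150G>A", "p.V50V", allele_count=4, position=29172939),
        make_row("c.274C>T", "p.Q92Ter", allele_count=2, position=29175156),
        make_row("c.100+1G>T", allele_count=1),
        make_row("c.337-8G>C", allele_count=3),
        make_row("c.-12G>A", allele_count=5),
        make_row("c.118G>A", "p.V40Gfs", allele_count=1),  # frameshift marker
    ]
    return CohortTable(database_name="synthetic", unit=CountUnit.ALLELES, rows=rows)


@pytest.fixture
def toy_vcf(tmp_path):
    """Small uncompressed VCF with plain and population-suffixed counts."""
    text = textwrap.dedent("""\
        ##fileformat=VCFv4.2
        ##contig=<ID=chr18,length=78077248>
        ##INFO=<ID=AC,Number=A,Type=Integer,Description="Allele count">
        ##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number">
        ##INFO=<ID=nhomalt,Number=A,Type=Integer,Description="Homozygote count">
        ##INFO=<ID=AC_afr,Number=A,Type=Integer,Description="Allele count, African/African-American">
        ##INFO=<ID=AN_afr,Number=1,Type=Integer,Description="Allele number, African/African-American">
        ##INFO=<ID=nhomalt_afr,Number=A,Type=Integer,Description="Homozygote count, African/African-American">
        #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
        chr18\t29172937\t.\tG\tA\t.\tPASS\tAC=2;AN=20;nhomalt=1
        chr18\t29178618\t.\tG\tA\t.\tPASS\tAC=435;AN=251496;nhomalt=3;AC_afr=402;AN_afr=24974;nhomalt_afr=3
        chr18\t29175144\t.\tA\tT,C\t.\tPASS\tAC=5,2;AN=251496;nhomalt=0,0
        """)
    path = tmp_path / "toy.vcf"
    path.write_text(text)
    return path
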