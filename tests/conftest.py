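import pytest

from vcfstack import FixtureSpec, ParseLevel, VariantStore, generate, read_truth, read_vcf

# Hand-written miniature VCF exercising flags, multi-allelics, missing values,
# undeclared keys, phased/unphased/hemizygous genotypes, and chr-prefix mixing.
TINY_VCF = """\
##fileformat=VCFv4.2
##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">
##INFO=<ID=DB,Number=0,Type=Flag,Description="dbSNP membership">
##INFO=<ID=CLASS,Number=1,Type=String,Description="Function class">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##contig=<ID=1>
##contig=<ID=2>
##contig=<ID=X>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tFATHER\tMOTHER\tCHILD
1\t101\trs1\tA\tG\t50\tPASS\tAF=0.01;DP=20;DB;CLASS=missense\tGT:DP\t0/1:30\t0|1:28\t1/1:31
1\t150\t.\tCA\tCT\t.\tq10;s50\tAF=0.5;DP=15\tGT:DP\t0/0:10\t0/1:12\t0/1:9
chr1\t200\trs2\tG\tC,T\t99.5\tPASS\tAF=0.1,0.005;CLASS=nonsense;XYZ=foo\tGT:DP\t1/2:40\t0/1:41\t0/2:39
2\t300\t.\tT\tA\t12.3\tlowDP\tAF=.;DP=.\tGT:DP\t./.:.\t0/0:22\t0/1:.
X\t500\t.\tG\tA\t88\tPASS\tAF=0.001;CLASS=missense\tGT:DP\t0\t0/1:20\t1
"""


@pytest.fixture
def tiny_vcf_path(tmp_path):
    path = tmp_path / "tiny.vcf"
    path.write_text(TINY_VCF)
    return path


@pytest.fixture
def tiny_store(tiny_vcf_path):
    header, records = read_vcf(tiny_vcf_path, ParseLevel.L2)
    return VariantStore.load(header, records)


@pytest.fixture(scope="session")
def big_fixture(tmp_path_factory):
    """The default study-scale fixture: 10,000-variant trio with planted truth."""
    outdir = tmp_path_factory.mktemp("bigfix")
    spec = FixtureSpec()
    paths = generate(spec, outdir)
    return {"spec": spec, "paths": paths, "dir": str(outdir)}


@pytest.fixture(scope="session")
def big_store(big_fixture):
    """Read-only store over the big fixture; tests must not mutate it."""
    header, records = read_vcf(big_fixture["paths"]["trio"], ParseLevel.L2)
    return VariantStore.load(header, records)


@pytest.fixture(scope="session")
def big_truth(big_fixture):
    return read_truth(big_fixture["paths"]["truth"])


@pytest.fixture
def fresh_big_store(big_fixture):
    """A mutable reload of the big fixture for annotation tests."""
    header, records = read_vcf(big_fixture["paths"]["trio"], ParseLevel.L2)
    return VariantStore.load(header, records)


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("smallfix")
    spec = FixtureSpec(n_variants=1000, seed=11, ann_overlap=120,
                       whitelist_overlap=25)
    paths = generate(spec, outdir)
    return {"spec": spec, "paths": paths, "dir": str(outdir)}


@pytest.fixture
def small_store(small_fixture):
    header, records = read_vcf(small_fixture["paths"]["trio"], ParseLevel.L2)
    return VariantStore.load(header, records)
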