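import pytest

from couplescreen import fixture_classification, fixture_panel, generate_couple_vcf


@pytest.fixture(scope="session")
def panel():
    return fixture_panel()


@pytest.fixture(scope="session")
def classification():
    return fixture_classification()


@pytest.fixture(scope="session")
def generated_couple(tmp_path_factory, panel):
    """A synthetic couple (2 planted PLPs, 1 decoy per class) on disk."""
    out_dir = tmp_path_factory.mktemp("synthetic_couple")
    return generate_couple_vcf(2, 1, panel, seed=7, out_dir=out_dir)


def write_vcf(path, records, samples=("P1", "P2")):
    """Write a minimal annotated VCF for tests.

    ``records`` are (chrom, pos, ref, alt_field, info, *genotypes) tuples.
    """
    header = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=1,length=249250621>\n"
        "##contig=<ID=chr2,length=243199373>\n"
        '##INFO=<ID=GENE,Number=A,Type=String,Description="g">\n'
        '##INFO=<ID=HGVSC,Number=A,Type=String,Description="c">\n'
        '##INFO=<ID=HGVSP,Number=A,Type=String,Description="p">\n'
        '##INFO=<ID=AF,Number=A,Type=Float,Description="af">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples) + "\n"
    )
    lines = [header]
    for chrom, pos, ref, alt, info, *gts in records:
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info or '.'}\tGT\t"
            + "\t".join(gts) + "\n"
        )
    path.write_text("".join(lines))
    return path
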