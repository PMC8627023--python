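import numpy as np
import pytest

from mexpred.synthetic import ShiftScenario, generate_domains, generate_tracks

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1>
##contig=<ID=chr2>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


@pytest.fixture
def make_vcf(tmp_path):
    """Write a throwaway VCF from (chrom, pos, ref, alt) tuples."""

    def _write(rows, name="test.vcf"):
        path = tmp_path / name
        body = "".join(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\n"
            for chrom, pos, ref, alt in rows
        )
        path.write_text(VCF_HEADER + body)
        return path

    return _write


@pytest.fixture(scope="session")
def toy_tracks():
    return generate_tracks(n_chroms=2, chrom_length=4000, n_records=20, seed=7)


@pytest.fixture(scope="session")
def default_domains():
    scenario = ShiftScenario(seed=1)
    source, target, hidden = generate_domains(scenario)
    return scenario, source, target, hidden


@pytest.fixture
def rng():
    return np.random.default_rng(42)
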