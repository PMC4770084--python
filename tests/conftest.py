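import numpy as np
import pytest
from pyfaidx import Fasta

from cmmltools.models import SomaticVariant
from cmmltools.simulate import CohortSimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One desk-scale synthetic cohort shared by read-only tests."""
    cfg = CohortSimConfig(seed=101, contig_length=1_000_000)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_fasta(tmp_path_factory):
    """A two-contig reference with known sequence."""
    path = tmp_path_factory.mktemp("ref") / "ref.fa"
    with open(path, "w") as fh:
        fh.write(">chr1\nAACGTACGTTGCANNA\n>chr2\nacgtacgt\n")
    return Fasta(str(path))


def make_variant(chrom="chr1", pos=100, ref="C", alt="T", patient="P1", **kw):
    return SomaticVariant(
        chrom=chrom, pos=pos, ref=ref, alt=alt, patient_id=patient, **kw
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
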