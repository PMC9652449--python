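import numpy as np
import pytest

from editquant import AmpliconReference
from editquant.pipeline import demo_data_path
from editquant.io import read_references

# Test amplicon built by hand: every base pair around the cut site is
# distinct from its neighbour, so 1-bp indels at offsets -3..+3 never shift
# under left alignment and window-boundary checks are exact.  Protospacer
# GTCAGTCAGTCAGTACGAGT has adenines at positions 4, 8 (editing window) and
# 12, 15, 18 (bystanders).
_PREFIX = "ATGCATCGATCGTAGCTAGCTAGGATCCGATCGATCGTAC"  # 40 bp
_PROTO = "GTCAGTCAGTCAGTACGAGT"
_PAM = "AGG"
_SUFFIX = "CATCGGATTACGGATCCGTACGATCGTAGCATCGATC"  # 37 bp


@pytest.fixture(scope="session")
def tref() -> AmpliconReference:
    return AmpliconReference(
        name="test_site",
        sequence=_PREFIX + _PROTO + _PAM + _SUFFIX,
        protospacer_start=40,
        strand="+",
        pam=_PAM,
    )


@pytest.fixture(scope="session")
def demo_refs():
    return read_references(
        demo_data_path("demo_amplicons.fasta"), demo_data_path("demo_amplicons.tsv")
    )


@pytest.fixture(scope="session")
def demo_ref(demo_refs):
    return demo_refs["demo_site1"]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(4, size=n)])
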