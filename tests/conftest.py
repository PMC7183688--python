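import numpy as np
import pandas as pd
import pytest

from epikit.genotype_io import SnpSpec, SubjectTable

# rs2230926-like: rare variant, risk allele = minor G
SNP_RARE = SnpSpec("snpA", allele_major="T", allele_minor="G", allele_risk="G")
# rs131654-like: common variant, risk allele = MAJOR T
SNP_COMMON = SnpSpec("snpB", allele_major="T", allele_minor="G", allele_risk="T")


@pytest.fixture
def snp_rare():
    return SNP_RARE


@pytest.fixture
def snp_common():
    return SNP_COMMON


@pytest.fixture
def toy_table(snp_rare, snp_common):
    """Six subjects spanning all genotype combinations of interest."""
    frame = pd.DataFrame({
        "sample_id": [f"P{i}" for i in range(6)],
        "status": [0, 0, 0, 1, 1, 1],
        "age": [40.0, 35.0, 50.0, 30.0, 28.0, 45.0],
        "sex": [1, 0, 1, 1, 1, 0],
        "snpA": ["TT", "TG", "GG", "TT", "GT", "GG"],
        "snpB": ["TT", "TG", "GG", "GG", "TG", "TT"],
    })
    return SubjectTable(frame, [snp_rare, snp_common])


def random_2x2x2_table(rng: np.random.Generator) -> np.ndarray:
    """Non-degenerate random cell counts: (exposureA, exposureB, status)."""
    return rng.integers(5, 200, size=(2, 2, 2))
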