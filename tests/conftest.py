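import numpy as np
import pandas as pd
import pytest

from growthpanel import GenotypeMatrix, PanelDefinition, default_panel
from growthpanel.records import MISSING


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_panel():
    """Five-gene panel covering AD / AR / XL and LOF / non-LOF genes."""
    return PanelDefinition(
        pd.DataFrame(
            {
                "gene": ["ACAN", "CUL7", "FANCB", "PTPN11", "PEX2"],
                "category": [
                    "SS disease", "SS disease", "SS disease",
                    "SS disease", "growth pathway",
                ],
                "inheritance": ["AD", "AR", "XL", "AD", "AR"],
                "lof_mechanism": [1, 1, 1, 0, 1],
            }
        )
    )


def make_matrix(dosages, group=None, sex=None, variant_ids=None, sample_ids=None):
    """Small-matrix builder for hand-constructed genotype tests."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    return GenotypeMatrix(
        d,
        sample_ids or [f"s{i}" for i in range(n)],
        variant_ids or [f"v{j}" for j in range(m)],
        group if group is not None else ["case"] * (n // 2) + ["control"] * (n - n // 2),
        sex if sex is not None else ["female"] * n,
    )


@pytest.fixture
def matrix_builder():
    return make_matrix
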