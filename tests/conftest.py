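import numpy as np
import pytest

from mhcgate.encoders import PseudoSequenceTable
from mhcgate.model import GatedMultiTaskModel, ModelConfig


@pytest.fixture(scope="session")
def pseudo_table() -> PseudoSequenceTable:
    table = PseudoSequenceTable()
    rng = np.random.default_rng(42)
    residues = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    for allele in ("HLA-A*02:01", "HLA-B*07:02", "HLA-C*07:01"):
        table.add(allele, "".join(rng.choice(residues, size=37)))
    return table


@pytest.fixture(scope="session")
def default_model() -> GatedMultiTaskModel:
    """An untrained model with the printed default architecture."""
    return GatedMultiTaskModel(ModelConfig(seed=1))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
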