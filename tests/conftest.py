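import numpy as np
import pandas as pd
import pytest

from integrotax.simulate import three_species_preset
from integrotax.tables import MorphoTable


@pytest.fixture(scope="session")
def preset():
    """The three-species synthetic dataset used across integration tests."""
    return three_species_preset(seed=7)


@pytest.fixture
def toy_morpho():
    """Six specimens, two groups, one missing cell, exact allometry in 'HL'."""
    ids = [f"s{i}" for i in range(1, 7)]
    sl = [40.0, 50.0, 60.0, 45.0, 55.0, 65.0]
    hl = [2 * s for s in sl]      # exactly 2*SL
    hl[2] = np.nan                # to be imputed at SL=60 -> 120
    plates = [24, 24.5, 25, 26, 27, 26.5]
    values = pd.DataFrame({"SL": sl, "HL": hl, "plates": plates}, index=ids)
    groups = pd.Series(["g1"] * 3 + ["g2"] * 3, index=ids)
    kinds = {"SL": "SL", "HL": "morphometric_SL", "plates": "meristic"}
    return MorphoTable(values, groups, kinds)
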