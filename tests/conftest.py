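import numpy as np
import pandas as pd
import pytest

from hcscreen import ImageGenParams, ScreenDesign, generate_field, simulate_screen


@pytest.fixture(scope="session")
def fifty_cell_field():
    """Default-SNR field with 50 cells, ~30% infected, plus its truth."""
    params = ImageGenParams(n_cells=50)
    return generate_field(params, infect_prob=0.3, seed=11)


@pytest.fixture(scope="session")
def default_screen():
    """One default-design simulated screen (wells table + planted truth)."""
    return simulate_screen(ScreenDesign(), seed=7)


@pytest.fixture()
def toy_plate() -> pd.DataFrame:
    """A hand-built plate: controls at known medians plus two test wells.

    Negative-control median 0.02, positive-control median 0.08, so a test
    efficiency of 0.05 normalizes to 0.5 and 0.11 to 1.5.
    """
    rows = []
    for i, eff in enumerate([0.01, 0.02, 0.03]):
        rows.append(("P01", f"A{i + 1:02d}", "neg_control", "", "", eff, 2000))
    for i, eff in enumerate([0.07, 0.08, 0.09]):
        rows.append(("P01", f"B{i + 1:02d}", "pos_control", "", "", eff, 2000))
    rows.append(("P01", "C01", "test", "G1_sh1", "G1", 0.05, 2000))
    rows.append(("P01", "C02", "test", "G1_sh2", "G1", 0.11, 2000))
    return pd.DataFrame(
        rows,
        columns=[
            "plate_id",
            "well_id",
            "role",
            "shrna_id",
            "gene_id",
            "efficiency",
            "cell_count",
        ],
    )
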