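import logging

import numpy as np
import pandas as pd
import pytest

from naiveomics.io_formats import ExpressionMatrix, SampleDesign
from naiveomics.synthetic_data import SimulationConfig, simulate_study

logging.getLogger("naiveomics").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced-scale study keeping every structural feature of the design."""
    return SimulationConfig(seed=11, n_proteins=150, n_phosphosites=400,
                            n_metabolites=80, n_posttx=10, n_gsk3_substrates=12)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture()
def tiny_design() -> SampleDesign:
    """Two plexes, each with an S/L reference and two treated channels."""
    rows = []
    for c in (1, 2):
        rows.append((f"CL{c}_SL", f"CL{c}", "SL", 0.0, f"plex{c}", 1))
        rows.append((f"CL{c}_2i", f"CL{c}", "2i", 1.0, f"plex{c}", 1))
        rows.append((f"CL{c}_Cdk8i", f"CL{c}", "Cdk8i", 1.0, f"plex{c}", 1))
    return SampleDesign(pd.DataFrame(rows, columns=[
        "sample_id", "cell_line", "treatment", "timepoint", "plex", "replicate"]))


def make_matrix(design: SampleDesign, values: np.ndarray,
                features=None, layer="protein") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    features = features or [f"F{i}" for i in range(values.shape[0])]
    frame = pd.DataFrame(values, index=features, columns=design.sample_ids)
    return ExpressionMatrix(frame, design, layer)
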