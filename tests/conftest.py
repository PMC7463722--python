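import numpy as np
import pandas as pd
import pytest

from acidadapt.simulate import (
    CellLineSimConfig,
    EffectSizeDistribution,
    simulate_cellline_counts,
)


@pytest.fixture(scope="session")
def small_design() -> pd.DataFrame:
    """3 cell lines x 2 pH x 3 replicates, the standard 18-sample layout."""
    rows = []
    for line in ("CL1", "CL2", "CL3"):
        for ph in ("control", "acid"):
            for rep in (1, 2, 3):
                rows.append(
                    {"sample_id": f"{line}_{ph}_r{rep}", "cell_line": line,
                     "ph": ph, "replicate": rep}
                )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def planted_simulation():
    """A 2000-gene simulation with a planted +/-2 log2FC on 5% of genes."""
    config = CellLineSimConfig(
        n_genes=2000,
        frac_responsive=0.05,
        effect_size_distribution=EffectSizeDistribution(location=2.0, scale=0.0, prob_up=0.6),
        dispersion=0.05,
        seed=42,
    )
    return simulate_cellline_counts(config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
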