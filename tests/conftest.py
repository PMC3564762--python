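import pandas as pd
import pytest

from aqpmeta.synthetic import SimulationConfig, simulate_expression


@pytest.fixture(scope="session")
def small_simulation():
    """A small noiseless collection shared by read-only tests."""
    config = SimulationConfig(
        n_genes=20, n_pairs=4, n_experiments=3, noise_sd=0.0, seed=7
    )
    return simulate_expression(config)


@pytest.fixture()
def toy_design():
    rows = []
    for cond in ("control", "drought"):
        for r in range(2):
            rows.append(
                {
                    "sample": f"e1_{cond}_r{r}",
                    "experiment": "e1",
                    "condition": cond,
                    "tissue": "leaf",
                    "cue_category": "abiotic stress",
                    "genotype": "wt",
                    "timepoint": "",
                }
            )
    return pd.DataFrame(rows)
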