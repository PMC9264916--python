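import numpy as np
import pandas as pd
import pytest

import hugescreen as hs


@pytest.fixture
def toy_essentiality() -> hs.EssentialityMatrix:
    """3 knockouts x 4 cell lines with one missing entry."""
    values = np.array(
        [
            [-3.0, -2.5, 0.5, 0.0],
            [-1.0, np.nan, -1.2, -0.8],
            [0.2, 0.1, -0.1, 0.3],
        ]
    )
    return hs.EssentialityMatrix(
        gene_ids=["KO1", "KO2", "KO3"],
        sample_ids=["A", "B", "C", "D"],
        values=values,
    )


@pytest.fixture
def hub_screen() -> hs.SyntheticScreen:
    """Small hub-structured screen shared across tests (fixed seed)."""
    return hs.simulate_screen(hs.SimulationConfig(seed=7))


@pytest.fixture
def hub_results(hub_screen) -> pd.DataFrame:
    return hs.moderated_t_test(hub_screen.essentiality, hub_screen.mutations)


def make_variant_table(rows) -> hs.VariantTable:
    return hs.VariantTable(
        pd.DataFrame(
            rows,
            columns=["sample_id", "gene", "variant_class", "allelic_fraction", "common", "neutral"],
        )
    )


@pytest.fixture
def edge_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_a": ["A", "A", "B"],
            "gene_b": ["B", "C", "C"],
            "combined_score": [400, 450, 450],
        }
    )
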