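import pandas as pd
import pytest

from hccsig import CohortConfig, simulate_expression


@pytest.fixture(scope="session")
def default_cohort():
    """The study-scale synthetic cohort (55/13/42 tumors, 14 livers, 41x2 tissues)."""
    config = CohortConfig(seed=1)
    expr, sheet, probe_map, truth = simulate_expression(config)
    return config, expr, sheet, probe_map, truth


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for fast structural tests."""
    config = CohortConfig(
        n_genes=200,
        n_planted_per_class={c: 8 for c in
                             ("tumor_specific", "tumor_associated",
                              "liver_specific", "down_in_tumor")},
        seed=7,
    )
    expr, sheet, probe_map, truth = simulate_expression(config)
    return config, expr, sheet, probe_map, truth


def planted(truth: pd.Series, cls: str) -> set[str]:
    return set(truth.index[truth == cls])
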