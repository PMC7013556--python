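import numpy as np
import pandas as pd
import pytest

from trophodiff.de import ExpressionMatrix, build_de_table
from trophodiff.synthetic import (
    ModuleSpec,
    SyntheticConfig,
    generate_timecourse,
)


def matrix_from_day_values(values: dict[int, np.ndarray]) -> ExpressionMatrix:
    """Build an ExpressionMatrix from {day: (genes × reps) array}."""
    cols, data = [], []
    for d, arr in sorted(values.items()):
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        for r in range(arr.shape[1]):
            cols.append(f"day{d}_rep{r + 1}")
            data.append(arr[:, r])
    frame = pd.DataFrame(
        np.column_stack(data),
        index=[f"g{i}" for i in range(len(data[0]))],
        columns=cols,
    )
    return ExpressionMatrix(frame)


# three mutually distinguishable shapes (no mirror pairs) for unsigned tests
THREE_SHAPE_MODULES = (
    ModuleSpec("immediate_transient_up", 50),
    ModuleSpec("immediate_persistent_up", 50),
    ModuleSpec("slow_persistent_up", 50),
)


@pytest.fixture(scope="session")
def noise_free_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_genes=1000, rep_sigma=0.0, seed=7,
        module_spec=THREE_SHAPE_MODULES,
        ppe_fraction_by_module=(0.05, 0.05, 0.3),
    )


@pytest.fixture(scope="session")
def noise_free_data(noise_free_config):
    return generate_timecourse(noise_free_config)


@pytest.fixture(scope="session")
def small_synthetic():
    """Default-design synthetic dataset at reduced size, with its DE table."""
    cfg = SyntheticConfig(
        n_genes=1200, seed=11,
        module_spec=(
            ModuleSpec("immediate_persistent_down", 160),
            ModuleSpec("immediate_persistent_up", 80),
            ModuleSpec("immediate_transient_up", 60),
            ModuleSpec("slow_persistent_up", 100),
            ModuleSpec("slow_persistent_down", 40),
        ),
        ppe_fraction_by_module=(0.02, 0.02, 0.02, 0.2, 0.1),
    )
    expr, ann, truth = generate_timecourse(cfg)
    de = build_de_table(expr)
    return cfg, expr, ann, truth, de
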