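import numpy as np
import pytest

from regennet import ExpressionMatrix, TimeDesign


@pytest.fixture
def design_2x2() -> TimeDesign:
    """Two time points, two replicates each (minimal ANOVA-capable design)."""
    return TimeDesign((0.0, 1.0), (2, 2))


@pytest.fixture
def design_dpi() -> TimeDesign:
    """The heart/cerebellum regeneration sampling grid: 0, 0.25, 1, 3 dpi."""
    return TimeDesign.uniform((0.0, 0.25, 1.0, 3.0), 2)


@pytest.fixture
def small_matrix(design_dpi) -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    values = rng.uniform(0.5, 10.0, size=(5, design_dpi.n_samples))
    ids = tuple(f"prot{i}" for i in range(5))
    return ExpressionMatrix(ids, design_dpi, values, condition_label="heart")
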