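import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from etch.expression_io import StageExpressionMatrix
from etch.synthetic_data import ArchetypeSpec, generate_stage_matrix

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


TWO_ARCHETYPES = (
    ArchetypeSpec("decay", (8.0, 4.0, 2.0, 1.0, 0.5, 0.2, 0.1), n_genes=50),
    ArchetypeSpec("pulse8c", (0.5, 0.5, 1.0, 2.0, 10.0, 2.0, 1.0), n_genes=50),
)


@pytest.fixture
def noiseless_two_archetype_matrix():
    """100 genes, two trajectory shapes, no noise: exact recovery is possible."""
    return generate_stage_matrix(TWO_ARCHETYPES, noise_log_sd=0.0, seed=11)


@pytest.fixture
def noisy_matrix():
    """Default six-archetype matrix with moderate multiplicative noise."""
    return generate_stage_matrix(noise_log_sd=0.25, seed=7)


@pytest.fixture
def tiny_matrix():
    """Hand-sized matrix for IO round-trips."""
    data = pd.DataFrame(
        [[10.0, 5.0, 2.5, 1.0, 0.5, 0.25, 0.125], [0.0, 1.0, 8.0, 2.0, 1.0, 0.5, 0.5]],
        index=["geneA", "geneB"],
        columns=["oocyte", "zygote", "2C", "4C", "8C", "morula", "blastocyst"],
    )
    return StageExpressionMatrix(data)
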