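import numpy as np
import pandas as pd
import pytest

from recovnet import StudyDesign, gen_expression_study


@pytest.fixture
def small_design():
    """20-gene study, 8 dysregulated, zero noise: planted values are exact."""
    return StudyDesign.from_counts(
        n_genes=20, n_disease_genes=8,
        arm_eor={"CF": 40.0, "BBP": -20.0, "CF+BBP": 100.0},
        noise_cv=0.0, seed=7)


@pytest.fixture
def small_study(small_design):
    return gen_expression_study(small_design)


@pytest.fixture
def readouts_exact():
    """Zero-noise assay readouts with planted effects (0.3, 0.4, 0.8)."""
    from recovnet import gen_assay
    table, truth = gen_assay({"CF": 0.3, "BBP": 0.4, "CF+BBP": 0.8},
                             n_replicates=3, noise_sd=0.0, seed=1,
                             mono_arms=("CF", "BBP"), combo="CF+BBP")
    return table, truth
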