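import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from modfuse import MODALITY_ORDER, SyntheticSpec, generate_multimodal


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def small_dataset():
    """Compact 4-modality dataset with planted signal in every modality."""
    spec = SyntheticSpec(
        n_per_class=(15, 15, 15),
        modality_dims={"MRI": 20, "PET": 20, "CSF": 3, "SNP": 30},
        informative_counts={"MRI": 4, "PET": 4, "CSF": 3, "SNP": 4},
        effect_sizes={m: 1.5 for m in MODALITY_ORDER},
        seed=11,
    )
    return generate_multimodal(spec)


@pytest.fixture(scope="session")
def noise_dataset():
    """Pure-noise dataset: every effect size zero."""
    spec = SyntheticSpec(
        n_per_class=(15, 15, 15),
        modality_dims={"MRI": 10, "PET": 10, "CSF": 3, "SNP": 20},
        informative_counts={"MRI": 0, "PET": 0, "CSF": 0, "SNP": 0},
        effect_sizes={m: 0.0 for m in MODALITY_ORDER},
        seed=12,
    )
    return generate_multimodal(spec)
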